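"""High-affinity model: α-amplification, reduction limit, bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from il15sim import (
    Dose,
    GeometryConstants,
    HighAffinityParams,
    HighAffinityState,
    IntermediateParams,
    IntermediateState,
    fold_change_profile,
    high_affinity_rhs,
    intermediate_rhs,
    simulate_high_affinity,
    simulate_intermediate,
    total_surface_complexes,
)
from tests.conftest import ASSAY_DOSES


class TestRhs:
    def test_reduces_to_intermediate_without_alpha_synthesis(self, geometry):
        p = HighAffinityParams(k_syn_p=0.0)
        p_int = IntermediateParams()
        s = HighAffinityState(R_s=500.0, C_s=60.0, R_e=100.0, C_e=5.0,
                              L=1e-9, L_e=1e-8)
        s_int = IntermediateState(R_s=500.0, C_s=60.0, R_e=100.0, C_e=5.0,
                                  L=1e-9, L_e=1e-8)
        d = high_affinity_rhs(s, p, geometry)
        d_int = intermediate_rhs(s_int, p_int, geometry)
        for name in ("R_s", "C_s", "R_e", "C_e", "L", "L_e"):
            assert getattr(d, name) == pytest.approx(getattr(d_int, name), rel=1e-12)

    def test_empty_cell_source_only(self, ha_params, geometry):
        d = high_affinity_rhs(HighAffinityState(R_s=0.0, L=0.0), ha_params, geometry)
        assert d.R_s == pytest.approx(ha_params.k_s)
        for name in ("C_s", "C_s_p", "Lam_s", "R_e", "C_e_p", "Lam_e"):
            assert getattr(d, name) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(R_s=st.floats(0, 1e4), C_s=st.floats(0, 1e3), C_s_p=st.floats(0, 1e3),
           Lam_s=st.floats(0, 1e3), Lam_e=st.floats(0, 1e3),
           C_e_p=st.floats(0, 1e3), R_e=st.floats(0, 1e4))
    def test_alpha_ledger_at_any_state(self, R_s, C_s, C_s_p, Lam_s, Lam_e,
                                       C_e_p, R_e):
        """d/dt(Λ_s + Λ_e + C_s' + C_e' + degraded-α) = k_syn'·(C_s + C_s')."""
        p, g = HighAffinityParams(), GeometryConstants()
        s = HighAffinityState(R_s=R_s, C_s=C_s, C_s_p=C_s_p, Lam_s=Lam_s,
                              Lam_e=Lam_e, C_e_p=C_e_p, R_e=R_e)
        d = high_affinity_rhs(s, p, g)
        alpha_rate = d.Lam_s + d.Lam_e + d.C_s_p + d.C_e_p + d.deg_Cp
        assert alpha_rate == pytest.approx(p.k_syn_p * (C_s + C_s_p),
                                           rel=1e-9, abs=1e-9)


class TestTrajectories:
    @pytest.mark.parametrize("dose", [9.0, 75.0])
    def test_reduction_equivalence_along_whole_trajectory(self, dose, geometry):
        p = HighAffinityParams(k_syn_p=0.0)
        grid = np.linspace(0.0, 48.0, 97)
        tc_int = simulate_intermediate(Dose(dose), IntermediateParams(), geometry,
                                       t_end=48.0, grid=grid)
        tc_ha = simulate_high_affinity(Dose(dose), p, geometry, t_end=48.0,
                                       grid=grid)
        for sp in ("R_s", "C_s", "R_e", "C_e", "L", "L_e"):
            a, b = tc_int.data[sp].to_numpy(), tc_ha.data[sp].to_numpy()
            scale = max(np.abs(a).max(), 1e-30)
            assert np.max(np.abs(a - b)) / scale < 1e-6

    def test_conservation_ledgers(self, ha_params, geometry):
        g = geometry
        tc = simulate_high_affinity(Dose(9.0), ha_params, g, t_end=96.0)
        df = tc.data
        ligand = (df["L"] * g.N_A * g.V_m
                  + g.N_tot * (df["L_e"] * g.N_A * g.V_e
                               + df["C_s"] + df["C_e"] + df["deg_C"]))
        assert np.max(np.abs(ligand / ligand.iloc[0] - 1)) < 1e-6
        beta = (df["R_s"] + df["C_s"] + df["R_e"] + df["C_e"] + df["C_s_p"]
                + df["C_e_p"] + df["deg_R"] + df["deg_C"] + df["deg_Cp"]
                - df["syn_total"])
        assert np.max(np.abs(beta - 800.0)) / 800.0 < 1e-6
        alpha = (df["Lam_s"] + df["Lam_e"] + df["C_s_p"] + df["C_e_p"]
                 + df["deg_Cp"] - df["syn_alpha"])
        assert np.max(np.abs(alpha)) < 1e-6 * max(df["syn_alpha"].max(), 1.0)


class TestSteadyState:
    def test_table_total_at_low_dose(self, high_affinity_ss):
        total = total_surface_complexes(high_affinity_ss[9.0].species)
        assert abs(total - 154) / 154 < 0.20

    def test_trimer_outnumbers_intermediate_threefold(self, high_affinity_ss):
        for d, ss in high_affinity_ss.items():
            ratio = ss.species["C_s_p"] / ss.species["C_s"]
            assert 2.0 <= ratio <= 4.0, f"ratio {ratio} at {d} ng/ml"

    def test_endosomal_trimer_accumulation(self, high_affinity_ss):
        """Trimeric complexes pile up in the endosome (slow dissociation)."""
        for ss in high_affinity_ss.values():
            assert ss.species["C_e_p"] > ss.species["C_e"]

    def test_fold_change_decreasing_and_above_one(self, ha_params, geometry):
        doses = [Dose(d) for d in (3.9, 9.0, 25.0, 75.0, 250.0, 2000.0)]
        fc = fold_change_profile(doses, ha_params, geometry)
        assert np.all(fc["fold_change"] >= 1.0)
        assert np.all(np.diff(fc["fold_change"]) < 0)
        # amplification is strongest where ligand is scarce
        assert fc["fold_change"].iloc[0] > 2 * fc["fold_change"].iloc[-1]

    def test_endosomal_lambda_mode_regression(self, geometry):
        """Per-molecule vs molar reading of the endosomal Λ on-rate: < 2%."""
        a = simulate_high_affinity(Dose(9.0), HighAffinityParams(), geometry,
                                   t_end=96.0).final_state()
        b = simulate_high_affinity(
            Dose(9.0), HighAffinityParams(kfe_p_mode="molar"), geometry,
            t_end=96.0).final_state()
        ta, tb = a["C_s"] + a["C_s_p"], b["C_s"] + b["C_s_p"]
        assert abs(ta - tb) / ta < 0.02


class TestTotalSurfaceComplexes:
    def test_sum_and_scaling(self):
        s = HighAffinityState(C_s=58.0, C_s_p=0.0)
        assert total_surface_complexes(s) == 58.0
        s2 = HighAffinityState(C_s=40.0, C_s_p=120.0)
        assert total_surface_complexes(s2) == 160.0
        assert total_surface_complexes({"C_s": 20.0, "C_s_p": 60.0}) == 80.0
        # linear under state scaling
        s3 = HighAffinityState(C_s=80.0, C_s_p=240.0)
        assert total_surface_complexes(s3) == pytest.approx(
            2 * total_surface_complexes(s2))

    def test_bad_input(self):
        with pytest.raises(TypeError):
            total_surface_complexes([1, 2])
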