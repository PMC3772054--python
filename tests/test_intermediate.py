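"""Intermediate-affinity model: dynamics, steady states, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from il15sim import (
    Dose,
    GeometryConstants,
    IntermediateParams,
    IntermediateState,
    ModelError,
    SteadyStateError,
    intermediate_rhs,
    kfe_from_kd_rule,
    simulate_intermediate,
    steady_state_intermediate,
)
from tests.conftest import ASSAY_DOSES, DOSE_GRID


class TestRhs:
    def test_source_only_from_empty_cell(self, params, geometry):
        d = intermediate_rhs(IntermediateState(R_s=0.0, L=0.0), params, geometry)
        assert d.R_s == pytest.approx(params.k_s)
        for name in ("C_s", "R_e", "C_e", "L", "L_e"):
            assert getattr(d, name) == 0.0

    def test_unstimulated_fixed_point(self, params, geometry):
        # R_s = k_s/k_endo balances constitutive synthesis and internalization
        st0 = IntermediateState(R_s=params.k_s / params.k_endo, L=0.0)
        d = intermediate_rhs(st0, params, geometry)
        for name in ("R_s", "C_s", "C_e", "L", "L_e"):
            assert getattr(d, name) == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(R_s=st.floats(0, 1e4), C_s=st.floats(0, 1e3), R_e=st.floats(0, 1e4),
           C_e=st.floats(0, 1e3), L=st.floats(0, 1e-7), L_e=st.floats(0, 1e-7))
    def test_receptor_balance_at_any_state(self, R_s, C_s, R_e, C_e, L, L_e):
        """d/dt(receptor units + degraded) equals the synthesis flux."""
        p, g = IntermediateParams(), GeometryConstants()
        d = intermediate_rhs(
            IntermediateState(R_s=R_s, C_s=C_s, R_e=R_e, C_e=C_e, L=L, L_e=L_e), p, g)
        units_rate = d.R_s + d.C_s + d.R_e + d.C_e + d.deg_R + d.deg_C
        assert units_rate == pytest.approx(p.k_s + p.k_syn * C_s, rel=1e-9)

    def test_invalid_states_rejected(self, params, geometry):
        with pytest.raises(ModelError):
            intermediate_rhs(IntermediateState(R_s=-1.0), params, geometry)
        with pytest.raises(ModelError):
            intermediate_rhs(IntermediateState(R_s=float("nan")), params, geometry)


class TestSimulate:
    def test_zero_dose_holds_resting_receptor_level(self, params, geometry):
        tc = simulate_intermediate(Dose(0.0), params, geometry, t_end=48.0)
        assert np.allclose(tc.data["R_s"], 800.0, rtol=1e-6)
        assert np.all(tc.data["C_s"] < 1e-12)  # integrator round-off only

    def test_initial_state_on_grid(self, params, geometry):
        tc = simulate_intermediate(Dose(25.0), params, geometry, t_end=10.0)
        assert tc.times[0] == 0.0
        assert tc.data["R_s"].iloc[0] == 800.0
        assert tc.data["C_s"].iloc[0] == 0.0

    def test_complexes_near_steady_state_after_6h(self, params, geometry,
                                                  intermediate_ss):
        tc = simulate_intermediate(Dose(25.0), params, geometry, t_end=48.0)
        target = intermediate_ss[25.0].C_s
        late = tc.data["C_s"][tc.times >= 6.0]
        assert np.all(np.abs(late - target) / target < 0.02)

    @pytest.mark.parametrize("dose", [3.9, 25.0, 2000.0])
    def test_conservation_ledgers(self, dose, params, geometry):
        g = geometry
        tc = simulate_intermediate(Dose(dose), params, g, t_end=48.0)
        df = tc.data
        assert (df[["R_s", "C_s", "R_e", "C_e", "L", "L_e"]] >= 0).all().all()
        ligand = (df["L"] * g.N_A * g.V_m
                  + g.N_tot * (df["L_e"] * g.N_A * g.V_e
                               + df["C_s"] + df["C_e"] + df["deg_C"]))
        assert np.max(np.abs(ligand / ligand.iloc[0] - 1)) < 1e-6
        receptors = (df["R_s"] + df["C_s"] + df["R_e"] + df["C_e"]
                     + df["deg_R"] + df["deg_C"] - df["syn_total"])
        assert np.max(np.abs(receptors - 800.0)) / 800.0 < 1e-6

    def test_accumulators_monotone(self, params, geometry):
        tc = simulate_intermediate(Dose(25.0), params, geometry, t_end=48.0)
        for col in ("deg_R", "deg_C", "syn_total"):
            assert np.all(np.diff(tc.data[col]) >= -1e-9)

    @pytest.mark.parametrize("dose", DOSE_GRID)
    def test_media_ligand_not_depleted(self, dose, params, geometry):
        tc = simulate_intermediate(Dose(dose), params, geometry, t_end=48.0)
        L = tc.data["L"]
        assert np.max(np.abs(L / L.iloc[0] - 1)) < 1e-3


class TestSteadyState:
    def test_printed_complex_numbers_reproduced(self, intermediate_ss):
        printed = {9.0: 58, 25.0: 116, 50.0: 160, 75.0: 184}
        for dose, expected in printed.items():
            got = intermediate_ss[dose].C_s
            assert abs(got - expected) / expected < 0.10

    def test_saturating_plateau(self, intermediate_ss):
        assert abs(intermediate_ss[2000.0].C_s - 257) / 257 < 0.15

    def test_matches_long_time_integration(self, params, geometry):
        for dose in DOSE_GRID:
            ss = steady_state_intermediate(Dose(dose), params, geometry,
                                           validate=True)
            assert ss.rel_diff_ode < 5e-3

    def test_monotone_in_dose(self, intermediate_ss):
        cs = [intermediate_ss[d].C_s for d in DOSE_GRID]
        rs = [intermediate_ss[d].R_s for d in DOSE_GRID]
        assert np.all(np.diff(cs) >= 0)
        assert np.all(np.diff(rs) <= 0)

    def test_surface_receptor_downregulation(self, intermediate_ss):
        """Total surface IL-15Rβγ drops below the resting 800 at any dose."""
        for d in DOSE_GRID:
            ss = intermediate_ss[d]
            assert ss.R_s + ss.C_s < 800.0

    def test_surface_complexes_exceed_endosomal(self, intermediate_ss):
        for d in DOSE_GRID:
            ss = intermediate_ss[d]
            assert ss.C_s > ss.species["C_e"]

    def test_high_dose_limit(self, params, geometry):
        ss = steady_state_intermediate(Dose(1e-4, "M"), params, geometry)
        limit = params.k_s / (params.k_int - params.k_syn)
        assert ss.C_s == pytest.approx(limit, rel=1e-3)

    def test_diverging_parameters_rejected(self, geometry):
        p = IntermediateParams(k_int=1.0, k_syn=1.2)
        with pytest.raises(SteadyStateError):
            steady_state_intermediate(Dose(25.0), p, geometry)

    def test_endosomal_binding_presets_agree(self, params, geometry):
        """Printed k_fe vs the K_d-rule value: surface steady state unmoved."""
        kfe_rule = kfe_from_kd_rule(params.k_f, params.k_r, params.k_re)
        assert kfe_rule == pytest.approx(9.0625e8, rel=1e-3)
        p_rule = IntermediateParams(k_fe=kfe_rule)
        for dose in ASSAY_DOSES:
            a = steady_state_intermediate(Dose(dose), params, geometry).C_s
            b = steady_state_intermediate(Dose(dose), p_rule, geometry).C_s
            assert abs(a - b) / a < 0.01


def test_tidy_csv_round_trip(tmp_path, params, geometry):
    import pandas as pd

    tc = simulate_intermediate(Dose(25.0), params, geometry, t_end=5.0)
    out = tmp_path / "tc.csv"
    tc.write_csv(out)
    df = pd.read_csv(out)
    assert set(df.columns) == {"time_h", "species", "value", "unit", "dose_ng_ml"}
    assert (df["dose_ng_ml"] == 25.0).all()
    cs = df[(df.species == "C_s")].sort_values("time_h")["value"].to_numpy()
    assert np.allclose(cs, tc.data["C_s"].to_numpy())
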