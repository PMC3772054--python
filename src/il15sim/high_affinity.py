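"""High-affinity IL-15 receptor model for activated (dividing) NK cells.

Activated NK cells upregulate IL-15Rα.  Because free IL-15 is in excess and
IL-15Rα binds it extremely tightly (K_d ≈ 38 pM, off-rate 0.05 h⁻¹), every α
subunit is treated as instantaneously IL-15-loaded: synthesis at rate
``k_syn_p·(C_s + C_s')`` directly produces a membrane-bound high-affinity
ligand Λ (the IL-15/IL-15Rα complex) with no free-α species.  Λ binds the
intermediate receptor IL-15Rβγ to form the trimeric signaling complex
``C_s'`` (IL-15/IL-15Rαβγ).

Membrane 2D binding uses the effective concentration ``xi_surf·Λ_s`` so the
surface on-rate ``k_f_p`` keeps molar units.  In the endosome the default
interpretation treats ``k_fe_p`` as a per-molecule pseudo-association rate
(flux ``k_fe_p·Λ_e·R_e``); an alternative molar interpretation with an
explicit ``xi_endo`` factor is selectable and changes steady-state totals
negligibly.  Λ recycles like soluble ligand and is never degraded on its
own; the trimeric complex is internalized (``k_int``) and degraded
(``k_deg``) as a unit, exactly like the intermediate complex.

With ``k_syn_p = 0`` and zero initial high-affinity species the system
reduces identically to the intermediate-affinity model.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from .intermediate import (
    IntermediateParams,
    IntermediateState,
    ModelError,
    SteadyStateSummary,
    Timecourse,
    _integrate,
)
from .units import Dose, GeometryConstants, dose_to_molar, percell_flux_to_media_rate

__all__ = [
    "HighAffinityParams",
    "HighAffinityState",
    "high_affinity_rhs",
    "simulate_high_affinity",
    "steady_state_high_affinity",
    "total_surface_complexes",
    "fold_change_profile",
]


@dataclass(frozen=True)
class HighAffinityParams(IntermediateParams):
    """Intermediate-model rate constants plus the high-affinity extension.

    ``kfe_p_mode`` selects the endosomal Λ-binding interpretation:
    ``"per_molecule"`` (flux k_fe_p·Λ_e·R_e, the default) or ``"molar"``
    (flux k_fe_p·xi_endo·Λ_e·R_e with k_fe_p read as M⁻¹h⁻¹).
    """

    k_f_p: float = 1.3e9     # Λ + Rβγ surface association, M^-1 h^-1
    k_r_p: float = 5.0e-2    # trimer surface dissociation, h^-1
    k_fe_p: float = 4.0e-4   # endosomal Λ association (per-molecule), h^-1
    k_re_p: float = 0.4      # endosomal trimer dissociation, h^-1
    k_syn_p: float = 1.5     # induced IL-15Rα (Λ) synthesis, h^-1
    kfe_p_mode: str = "per_molecule"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "kfe_p_mode":
                if self.kfe_p_mode not in ("per_molecule", "molar"):
                    raise ValueError(f"unknown kfe_p_mode {self.kfe_p_mode!r}")
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"rate constant {f.name} must be non-negative")


@dataclass(frozen=True)
class HighAffinityState(IntermediateState):
    """Intermediate-model species plus trimeric complexes and the Λ ligand.

    ``C_s_p``/``C_e_p`` are surface/endosomal IL-15/IL-15Rαβγ complexes,
    ``Lam_s``/``Lam_e`` the surface/endosomal high-affinity ligand, all in
    molecules/cell.  ``deg_Cp`` and ``syn_alpha`` extend the bookkeeping to
    the α-subunit ledger.
    """

    C_s_p: float = 0.0
    C_e_p: float = 0.0
    Lam_s: float = 0.0
    Lam_e: float = 0.0
    deg_Cp: float = 0.0
    syn_alpha: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array([
            self.R_s, self.C_s, self.R_e, self.C_e, self.L, self.L_e,
            self.C_s_p, self.C_e_p, self.Lam_s, self.Lam_e,
            self.deg_R, self.deg_C, self.deg_Cp, self.syn_total, self.syn_alpha,
        ])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "HighAffinityState":
        (R_s, C_s, R_e, C_e, L, L_e, C_s_p, C_e_p, Lam_s, Lam_e,
         deg_R, deg_C, deg_Cp, syn_total, syn_alpha) = map(float, y)
        return cls(R_s=R_s, C_s=C_s, R_e=R_e, C_e=C_e, L=L, L_e=L_e,
                   C_s_p=C_s_p, C_e_p=C_e_p, Lam_s=Lam_s, Lam_e=Lam_e,
                   deg_R=deg_R, deg_C=deg_C, deg_Cp=deg_Cp,
                   syn_total=syn_total, syn_alpha=syn_alpha)


SPECIES_HA = ["R_s", "C_s", "R_e", "C_e", "L", "L_e", "C_s_p", "C_e_p",
              "Lam_s", "Lam_e", "deg_R", "deg_C", "deg_Cp", "syn_total",
              "syn_alpha"]


def _rhs_ha(t, y, p: HighAffinityParams, g: GeometryConstants) -> np.ndarray:
    R_s, C_s, R_e, C_e, L, L_e, C_s_p, C_e_p, Lam_s, Lam_e = y[:10]
    bind_s = p.k_f * L * R_s
    bind_sp = p.k_f_p * (g.xi_surf * Lam_s) * R_s
    bind_e = p.k_fe * L_e * R_e
    if p.kfe_p_mode == "per_molecule":
        bind_ep = p.k_fe_p * Lam_e * R_e
    else:
        bind_ep = p.k_fe_p * (g.xi_endo * Lam_e) * R_e
    induced = p.k_syn * (C_s + C_s_p)

    dR_s = (p.k_s + induced - bind_s + p.k_r * C_s
            - bind_sp + p.k_r_p * C_s_p - p.k_endo * R_s)
    dC_s = bind_s - (p.k_r + p.k_int) * C_s
    dC_s_p = bind_sp - (p.k_r_p + p.k_int) * C_s_p
    dLam_s = (p.k_syn_p * (C_s + C_s_p) - bind_sp + p.k_r_p * C_s_p
              - p.k_endo * Lam_s + p.k_rec * Lam_e)
    dR_e = (p.k_endo * R_s + p.k_re * C_e - bind_e
            + p.k_re_p * C_e_p - bind_ep - p.k_deg * R_e)
    dC_e = p.k_int * C_s + bind_e - (p.k_re + p.k_deg) * C_e
    dC_e_p = p.k_int * C_s_p + bind_ep - (p.k_re_p + p.k_deg) * C_e_p
    dLam_e = p.k_endo * Lam_s + p.k_re_p * C_e_p - bind_ep - p.k_rec * Lam_e
    dL = (percell_flux_to_media_rate(p.k_r * C_s - bind_s, g)
          + p.k_rec * L_e * (g.V_e * g.N_tot / g.V_m))
    dL_e = (p.k_re * C_e - bind_e) / (g.N_A * g.V_e) - p.k_rec * L_e
    return np.array([
        dR_s, dC_s, dR_e, dC_e, dL, dL_e, dC_s_p, dC_e_p, dLam_s, dLam_e,
        p.k_deg * R_e,
        p.k_deg * C_e,
        p.k_deg * C_e_p,
        p.k_s + induced,
        p.k_syn_p * (C_s + C_s_p),
    ])


def high_affinity_rhs(state: HighAffinityState, p: HighAffinityParams,
                      g: GeometryConstants | None = None) -> HighAffinityState:
    """Time derivative of a :class:`HighAffinityState`."""
    g = g or GeometryConstants()
    y = state.to_vector()
    if np.any(np.isnan(y)):
        raise ModelError("state contains NaN")
    if np.any(y[:10] < 0):
        raise ModelError(f"negative species in state: {state}")
    return HighAffinityState.from_vector(_rhs_ha(0.0, y, p, g))


def simulate_high_affinity(dose: Dose, p: HighAffinityParams | None = None,
                           g: GeometryConstants | None = None,
                           t_end: float = 96.0, grid=None) -> Timecourse:
    """Integrate the high-affinity model from zero high-affinity species.

    The α-feedback loop (complexes induce Λ synthesis, Λ creates more
    complexes) makes the approach to steady state slower than in the
    intermediate model, so the default horizon is 96 h.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    p = p or HighAffinityParams()
    g = g or GeometryConstants()
    y0 = HighAffinityState(L=dose_to_molar(dose, g)).to_vector()
    grid, ys = _integrate(y0, t_end, grid, _rhs_ha, p, g, dose)
    if np.any(ys[:, :10] < -1e-6 * np.abs(ys[:, :10]).max()):
        raise ModelError(f"negative species in solution at dose {dose}")
    ys = np.clip(ys, 0.0, None)
    return Timecourse(grid, pd.DataFrame(ys, columns=SPECIES_HA), dose, p, g)


def _converged(tc: Timecourse, window: float = 1.0, tol: float = 1e-5) -> bool:
    """Max relative species change per hour at the end of the run < tol."""
    t = tc.times
    i = np.searchsorted(t, t[-1] - window)
    a = tc.data.iloc[i].to_numpy()
    b = tc.data.iloc[-1].to_numpy()
    scale = np.maximum(np.abs(b), 1e-30)
    main = slice(0, 10 if len(tc.data.columns) > 9 else 6)
    rel = (np.abs(b - a) / scale)[main] / max(t[-1] - t[i], 1e-12)
    return bool(np.max(rel) < tol)


def steady_state_high_affinity(dose: Dose, p: HighAffinityParams | None = None,
                               g: GeometryConstants | None = None) -> SteadyStateSummary:
    """Steady state of the high-affinity model by long-time integration.

    Integrates to 48 h, extends to 96 h if the trajectory has not settled,
    and reports the final state with a convergence flag.
    """
    p = p or HighAffinityParams()
    g = g or GeometryConstants()
    tc = simulate_high_affinity(dose, p, g, t_end=48.0)
    if not _converged(tc):
        tc = simulate_high_affinity(dose, p, g, t_end=96.0)
    end = tc.final_state()
    return SteadyStateSummary(dose, end, converged=_converged(tc),
                              method="ode-long-time")


def total_surface_complexes(state) -> float:
    """Total signaling complexes at the cell surface: ``C_s + C_s'``."""
    if isinstance(state, HighAffinityState):
        return state.C_s + state.C_s_p
    if isinstance(state, dict):
        return state["C_s"] + state.get("C_s_p", 0.0)
    raise TypeError(f"unsupported state type {type(state)!r}")


def fold_change_profile(doses, p: HighAffinityParams | None = None,
                        g: GeometryConstants | None = None) -> pd.DataFrame:
    """Per-dose amplification of total surface complexes by IL-15Rα.

    Returns a table with the intermediate-model steady-state ``C_s``, the
    high-affinity total ``C_s + C_s'`` and their ratio, which is ≥ 1 and
    decreases with dose (the α amplification matters most when soluble IL-15
    is scarce).
    """
    from .intermediate import steady_state_intermediate

    p = p or HighAffinityParams()
    g = g or GeometryConstants()
    p_int = IntermediateParams(**{f.name: getattr(p, f.name)
                                  for f in fields(IntermediateParams)})
    rows = []
    for dose in doses:
        inter = steady_state_intermediate(dose, p_int, g)
        if inter.C_s <= 0:
            raise ZeroDivisionError(
                f"fold change undefined at dose {dose}: intermediate C_s = 0")
        high = steady_state_high_affinity(dose, p, g)
        total = total_surface_complexes(high.species)
        rows.append({"dose_ng_ml": dose.value if dose.unit == "ng/ml" else None,
                     "C_s_intermediate": inter.C_s,
                     "total_high_affinity": total,
                     "fold_change": total / inter.C_s})
    return pd.DataFrame(rows)
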