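"""Intermediate-affinity IL-15 receptor binding/trafficking/synthesis model.

Quiescent NK cells express only the intermediate-affinity receptor IL-15Rβγ
(~800 copies per cell).  The model tracks six species — free surface receptor
``R_s``, surface complex ``C_s``, free endosomal receptor ``R_e``, endosomal
complex ``C_e``, media ligand ``L`` (M) and free endosomal ligand ``L_e`` (M)
— plus cumulative bookkeeping accumulators for degraded receptors/complexes
and synthesized receptors, used by conservation checks.

Reactions (mass action, rates in h⁻¹ or M⁻¹h⁻¹):

* surface binding ``k_f``/dissociation ``k_r``; endosomal ``k_fe``/``k_re``
  (affinity weakened at endosomal pH),
* constitutive receptor internalization ``k_endo``; ligand-induced complex
  internalization ``k_int`` (which replaces, not supplements, ``k_endo`` for
  bound receptor),
* recycling of free endosomal ligand at ``k_rec``; degradation of endosomal
  receptors and complexes at ``k_deg`` (a degraded complex destroys its
  ligand),
* constitutive synthesis ``k_s`` (molecules/cell/h) and complex-induced
  synthesis ``k_syn·C_s`` of new surface receptors.

All species are deterministic mean-field quantities and are never rounded to
integers.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace, asdict

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .units import Dose, GeometryConstants, dose_to_molar, percell_flux_to_media_rate

__all__ = [
    "IntermediateParams",
    "IntermediateState",
    "Timecourse",
    "SteadyStateSummary",
    "ModelError",
    "SteadyStateError",
    "intermediate_rhs",
    "simulate_intermediate",
    "steady_state_intermediate",
    "kfe_from_kd_rule",
]


class ModelError(RuntimeError):
    """Integration or state-validity failure, annotated with context."""


class SteadyStateError(ModelError):
    """No finite steady state exists for the given parameters."""


def kfe_from_kd_rule(k_f: float, k_r: float, k_re: float, fold: float = 8.0) -> float:
    """Endosomal on-rate implied by an ``fold``-times-weaker endosomal K_d.

    With the endosomal off-rate fixed, ``K_d,endo = fold * k_r/k_f`` gives
    ``k_fe = k_re * k_f / (fold * k_r)``.  This is an alternative preset to
    the tabulated ``k_fe``; order-of-magnitude changes in the endosomal
    binding rates leave the surface steady state essentially unchanged.
    """
    return k_re * k_f / (fold * k_r)


@dataclass(frozen=True)
class IntermediateParams:
    """Rate constants of the intermediate-affinity model (defaults: literature
    estimates for IL-15/IL-15Rβγ and IL-2-family receptor trafficking)."""

    k_f: float = 9.0e8     # surface association, M^-1 h^-1
    k_r: float = 3.6       # surface dissociation, h^-1
    k_fe: float = 2.9e-2   # endosomal association, M^-1 h^-1
    k_re: float = 29.0     # endosomal dissociation, h^-1
    k_s: float = 336.0     # constitutive synthesis, molecules/cell/h (= k_endo * 800)
    k_syn: float = 1.2     # induced synthesis, h^-1
    k_endo: float = 0.42   # constitutive internalization, h^-1
    k_int: float = 2.4     # complex internalization, h^-1
    k_rec: float = 7.4     # endosomal ligand recycling, h^-1
    k_deg: float = 2.1     # endosomal receptor/complex degradation, h^-1

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"rate constant {f.name} must be non-negative")

    def scaled(self, name: str, factor: float) -> "IntermediateParams":
        """Return a copy with one rate constant multiplied by ``factor``."""
        if name not in {f.name for f in fields(self)}:
            raise KeyError(f"unknown parameter {name!r}")
        return replace(self, **{name: getattr(self, name) * factor})

    @classmethod
    def from_config(cls, path) -> "IntermediateParams":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        return cls(**{k: float(v) for k, v in raw.items() if k in known})


@dataclass(frozen=True)
class IntermediateState:
    """Per-cell species counts plus bulk/endosomal ligand concentrations.

    ``deg_R``/``deg_C`` are cumulative degraded free receptors / complexes
    (molecules/cell) and ``syn_total`` the cumulative synthesized receptors;
    they are monotone accumulators used by the conservation tests.
    """

    R_s: float = 800.0
    C_s: float = 0.0
    R_e: float = 0.0
    C_e: float = 0.0
    L: float = 0.0       # M
    L_e: float = 0.0     # M
    deg_R: float = 0.0
    deg_C: float = 0.0
    syn_total: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array([self.R_s, self.C_s, self.R_e, self.C_e, self.L, self.L_e,
                         self.deg_R, self.deg_C, self.syn_total])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "IntermediateState":
        return cls(*map(float, y))


SPECIES = ["R_s", "C_s", "R_e", "C_e", "L", "L_e", "deg_R", "deg_C", "syn_total"]


def _rhs(t, y, p: IntermediateParams, g: GeometryConstants) -> np.ndarray:
    R_s, C_s, R_e, C_e, L, L_e = y[:6]
    bind_s = p.k_f * L * R_s
    bind_e = p.k_fe * L_e * R_e
    dR_s = p.k_s + p.k_syn * C_s - bind_s + p.k_r * C_s - p.k_endo * R_s
    dC_s = bind_s - (p.k_r + p.k_int) * C_s
    dR_e = p.k_endo * R_s + p.k_re * C_e - bind_e - p.k_deg * R_e
    dC_e = p.k_int * C_s + bind_e - (p.k_re + p.k_deg) * C_e
    dL = (percell_flux_to_media_rate(p.k_r * C_s - bind_s, g)
          + p.k_rec * L_e * (g.V_e * g.N_tot / g.V_m))
    dL_e = (p.k_re * C_e - bind_e) / (g.N_A * g.V_e) - p.k_rec * L_e
    return np.array([
        dR_s, dC_s, dR_e, dC_e, dL, dL_e,
        p.k_deg * R_e,            # degraded free receptors
        p.k_deg * C_e,            # degraded complexes (ligand destroyed with them)
        p.k_s + p.k_syn * C_s,    # synthesized receptors
    ])


def intermediate_rhs(state: IntermediateState, p: IntermediateParams,
                     g: GeometryConstants | None = None) -> IntermediateState:
    """Time derivative of an :class:`IntermediateState` (same field layout)."""
    g = g or GeometryConstants()
    y = state.to_vector()
    if np.any(np.isnan(y)):
        raise ModelError("state contains NaN")
    if np.any(y[:6] < 0):
        raise ModelError(f"negative species in state: {state}")
    return IntermediateState.from_vector(_rhs(0.0, y, p, g))


@dataclass
class Timecourse:
    """Solution of a model run on a strictly increasing time grid (h).

    ``data`` holds one column per species; ``data.iloc[0]`` equals the
    declared initial conditions.
    """

    times: np.ndarray
    data: pd.DataFrame
    dose: Dose
    params: object
    geometry: GeometryConstants

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def final_state(self) -> dict[str, float]:
        return self.data.iloc[-1].to_dict()

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: time_h, species, value, unit, dose_ng_ml."""
        from .units import molar_to_dose

        dose_ngml = molar_to_dose(dose_to_molar(self.dose, self.geometry),
                                  "ng/ml", self.geometry).value
        rows = self.data.copy()
        rows.insert(0, "time_h", self.times)
        long = rows.melt(id_vars="time_h", var_name="species", value_name="value")
        long["unit"] = np.where(long["species"].isin(["L", "L_e"]), "M", "molecules/cell")
        long["dose_ng_ml"] = dose_ngml
        return long

    def write_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False)


# absolute tolerances: molecule counts vs molar concentrations live on very
# different scales, so the integrator gets a per-component atol
def _atol(n_species: int, conc_idx: tuple[int, ...]) -> np.ndarray:
    atol = np.full(n_species, 1e-9)
    atol[list(conc_idx)] = 1e-22
    return atol


def _integrate(y0, t_end, grid, rhs, p, g, dose, rtol=1e-10):
    if grid is None:
        grid = np.linspace(0.0, t_end, max(int(t_end * 10), 50) + 1)
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must start at 0 and be strictly increasing")
    conc_idx = tuple(i for i, s in enumerate(SPECIES) if s in ("L", "L_e")) \
        if len(y0) == len(SPECIES) else (4, 5)
    sol = solve_ivp(rhs, (0.0, grid[-1]), y0, t_eval=grid, method="LSODA",
                    rtol=rtol, atol=_atol(len(y0), conc_idx), args=(p, g))
    if not sol.success:
        raise ModelError(
            f"integration failed at dose {dose} with params {p}: {sol.message}")
    return grid, sol.y.T


def simulate_intermediate(dose: Dose, p: IntermediateParams | None = None,
                          g: GeometryConstants | None = None,
                          t_end: float = 48.0, grid=None) -> Timecourse:
    """Integrate the intermediate-affinity model from the standard initial
    conditions (800 free surface receptors, everything else zero, media
    ligand set by ``dose``).

    Stiff-capable (LSODA) with relative tolerance 1e-10; output species are
    clipped of sub-tolerance negative round-off.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    p = p or IntermediateParams()
    g = g or GeometryConstants()
    y0 = IntermediateState(L=dose_to_molar(dose, g)).to_vector()
    grid, ys = _integrate(y0, t_end, grid, _rhs, p, g, dose)
    if np.any(ys[:, :6] < -1e-6 * np.abs(ys[:, :6]).max()):
        raise ModelError(f"negative species in solution at dose {dose}")
    ys = np.clip(ys, 0.0, None)
    return Timecourse(grid, pd.DataFrame(ys, columns=SPECIES), dose, p, g)


@dataclass
class SteadyStateSummary:
    """Steady-state species values at a given dose, with diagnostics."""

    dose: Dose
    species: dict[str, float]
    converged: bool
    method: str
    rel_diff_ode: float | None = None  # filled when cross-validated

    @property
    def C_s(self) -> float:
        return self.species["C_s"]

    @property
    def R_s(self) -> float:
        return self.species["R_s"]


def steady_state_intermediate(dose: Dose, p: IntermediateParams | None = None,
                              g: GeometryConstants | None = None,
                              validate: bool = False) -> SteadyStateSummary:
    """Algebraic steady state of the intermediate model.

    The media ligand is treated as fixed at the dose concentration (ligand
    depletion is negligible; see the non-depletion property).  The surface
    balance then has the closed form::

        C_s = k_f L R_s / (k_r + k_int)
        R_s = k_s / (k_f L + k_endo - (k_syn + k_r) k_f L / (k_r + k_int))

    which requires ``k_int > k_syn`` for a finite saturating plateau
    (``C_s -> k_s/(k_int - k_syn)`` as L grows).  The endosomal subsystem
    (R_e, C_e, L_e) is solved numerically from its own balance.

    With ``validate=True`` the result is cross-checked against a long-time
    integration and the maximum relative difference over the main species is
    recorded in ``rel_diff_ode``.
    """
    p = p or IntermediateParams()
    g = g or GeometryConstants()
    if p.k_int <= p.k_syn:
        raise SteadyStateError(
            f"k_int={p.k_int} <= k_syn={p.k_syn}: complexes grow without bound")
    L = dose_to_molar(dose, g)
    kfL = p.k_f * L
    denom = kfL + p.k_endo - (p.k_syn + p.k_r) * kfL / (p.k_r + p.k_int)
    if denom <= 0:
        raise SteadyStateError(
            f"no finite steady state at dose {dose}: surface balance diverges")
    R_s = p.k_s / denom
    C_s = kfL * R_s / (p.k_r + p.k_int)

    # endosomal fixed point given the surface fluxes
    C_e0 = p.k_int * C_s / (p.k_re + p.k_deg)
    R_e0 = (p.k_endo * R_s + p.k_re * C_e0) / p.k_deg if p.k_deg > 0 else 0.0
    L_e0 = p.k_re * C_e0 / (g.N_A * g.V_e * p.k_rec) if p.k_rec > 0 else 0.0

    def endo_balance(x):
        R_e, C_e, L_e = x
        bind_e = p.k_fe * L_e * R_e
        return [
            p.k_endo * R_s + p.k_re * C_e - bind_e - p.k_deg * R_e,
            p.k_int * C_s + bind_e - (p.k_re + p.k_deg) * C_e,
            (p.k_re * C_e - bind_e) / (g.N_A * g.V_e) - p.k_rec * L_e,
        ]

    R_e, C_e, L_e = fsolve(endo_balance, [R_e0, C_e0, L_e0], xtol=1e-12)
    species = {"R_s": R_s, "C_s": C_s, "R_e": float(R_e), "C_e": float(C_e),
               "L": L, "L_e": float(L_e)}
    summary = SteadyStateSummary(dose, species, converged=True, method="algebraic")
    if validate:
        tc = simulate_intermediate(dose, p, g, t_end=48.0)
        end = tc.final_state()
        diffs = [abs(end[k] - species[k]) / species[k]
                 for k in ("R_s", "C_s") if species[k] > 0]
        summary.rel_diff_ode = max(diffs) if diffs else 0.0
    return summary
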