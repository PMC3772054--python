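"""One-at-a-time parameter perturbation scans.

Each rate constant is scaled over a symmetric logarithmic factor grid
(1/100 … 100) while all others are held fixed, and the steady state is
re-evaluated at a reference dose (25 ng/ml).  Some perturbations destroy the
steady state altogether — e.g. reducing the complex internalization rate
k_int far enough that induced synthesis outruns removal, so complexes
accumulate at the surface without bound — and those grid points are flagged
rather than reported as numbers.

A companion scan co-varies k_f and k_r at a fixed equilibrium dissociation
constant K_d = k_r/k_f, which blunts (but does not remove) the complex gain
seen when k_f is raised alone.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .high_affinity import HighAffinityParams, _converged, simulate_high_affinity
from .intermediate import IntermediateParams, Timecourse, simulate_intermediate
from .units import Dose, GeometryConstants

__all__ = [
    "DEFAULT_FACTORS",
    "ScanResult",
    "scan_parameter",
    "scan_kf_kr_fixed_kd",
    "classify_steady_state",
]

DEFAULT_FACTORS = (1 / 100, 1 / 33, 1 / 10, 1 / 3, 1.0, 3.0, 10.0, 33.0, 100.0)

CONVERGED = "converged"
NON_CONVERGED = "non_converged"
DIVERGING = "diverging"


def classify_steady_state(tc: Timecourse) -> str:
    """Classify a timecourse as converged / non_converged / diverging.

    Converged: every main species changes by < 1e-5 relative over the final
    1 h window.  Diverging: the surface complex count is still growing
    super-linearly at the horizon (its increments increase window over
    window).  Anything else: non_converged.
    """
    if tc.times[-1] < 24.0:
        raise ValueError("classification requires a horizon of at least 24 h")
    if _converged(tc):
        return CONVERGED
    t = tc.times
    cs = tc.data["C_s"].to_numpy()
    if "C_s_p" in tc.data.columns:
        cs = cs + tc.data["C_s_p"].to_numpy()
    w = (t[-1] - t[0]) / 8
    i2 = np.searchsorted(t, t[-1] - w)
    i1 = np.searchsorted(t, t[-1] - 2 * w)
    d_late, d_early = cs[-1] - cs[i2], cs[i2] - cs[i1]
    if d_late > d_early > 0 and d_late > 1e-3 * max(cs[-1], 1.0):
        return DIVERGING
    return NON_CONVERGED


@dataclass
class ScanResult:
    """Steady-state summaries across a perturbation factor grid.

    ``table`` has one row per factor with the steady-state (or horizon)
    species values and a convergence flag; the factor-1.0 row is the
    unperturbed baseline.
    """

    model: str
    parameter: str
    dose: Dose
    table: pd.DataFrame

    def row(self, factor: float) -> pd.Series:
        idx = np.argmin(np.abs(self.table["factor"].to_numpy() - factor))
        return self.table.iloc[idx]


def _steady_row(model: str, p, g, dose: Dose) -> dict:
    if model == "intermediate":
        tc = simulate_intermediate(dose, p, g, t_end=48.0)
    else:
        tc = simulate_high_affinity(dose, p, g, t_end=96.0)
    flag = classify_steady_state(tc)
    end = tc.final_state()
    row = {"R_s": end["R_s"], "C_s": end["C_s"], "flag": flag}
    if "C_s_p" in end:
        row["C_s_p"] = end["C_s_p"]
        row["total_Cs"] = end["C_s"] + end["C_s_p"]
    else:
        row["total_Cs"] = end["C_s"]
    if flag == DIVERGING:
        # no steady state exists; horizon values are not meaningful numbers
        for k in ("R_s", "C_s", "C_s_p", "total_Cs"):
            if k in row:
                row[k] = np.nan
    return row


def _base_params(model: str, p):
    if p is not None:
        return p
    return IntermediateParams() if model == "intermediate" else HighAffinityParams()


def scan_parameter(model: str, name: str, factors=DEFAULT_FACTORS,
                   dose: Dose = Dose(25.0), p=None,
                   g: GeometryConstants | None = None) -> ScanResult:
    """Scale one rate constant over ``factors`` and record steady states."""
    if model not in ("intermediate", "high"):
        raise ValueError(f"unknown model {model!r}")
    p = _base_params(model, p)
    g = g or GeometryConstants()
    if name not in {f.name for f in fields(p)}:
        raise KeyError(f"unknown parameter {name!r} for model {model!r}")
    rows = []
    for factor in factors:
        rows.append({"param": name, "factor": factor,
                     **_steady_row(model, p.scaled(name, factor), g, dose)})
    return ScanResult(model, name, dose, pd.DataFrame(rows))


def scan_kf_kr_fixed_kd(factors=DEFAULT_FACTORS, dose: Dose = Dose(25.0),
                        p: IntermediateParams | None = None,
                        g: GeometryConstants | None = None,
                        model: str = "intermediate") -> ScanResult:
    """Co-scale k_f and k_r by the same factor, keeping K_d = k_r/k_f fixed."""
    p = _base_params(model, p)
    g = g or GeometryConstants()
    rows = []
    for factor in factors:
        if not factor > 0:
            raise ValueError("factors must be positive")
        p_f = p.scaled("k_f", factor).scaled("k_r", factor)
        rows.append({"param": "k_f&k_r", "factor": factor,
                     "K_d": p_f.k_r / p_f.k_f,
                     **_steady_row(model, p_f, g, dose)})
    return ScanResult(model, "k_f&k_r", dose, pd.DataFrame(rows))
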