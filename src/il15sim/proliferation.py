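"""From steady-state receptor occupancy to population proliferation.

The link between the receptor models and NK-cell population behaviour is a
cumulative-stimulus threshold: a quiescent cell commits to the cell cycle
once the area under its surface-complex curve, C_s·t (complex·h/cell, with
C_s at steady state within ~2 h), exceeds a fixed cell-cycle threshold.
The threshold is calibrated as the steady-state complex number at the lowest
reliably proliferative dose (9 ng/ml, ≈58 complexes/cell) times the 37.8 h
experimentally observed delay to first division, giving ≈2198 complex·h/cell.
Complete recruitment of the population requires the saturating stimulus
(≈257 complexes/cell × 64 h ≈ 16448 complex·h/cell).

Dividing cells re-use the same threshold: their interdivision time is the
threshold divided by their (higher, α-amplified) total surface complex
count, and the population mean division rate is half the maximal rate
1/t_div — the mean of an approximately Gaussian spread of per-cohort rates
running from the fastest cohort down to nearly zero.

The three time constants (37.8 h, 32 h, 64 h) are imported from independent
population-level analyses and are inputs here, not outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThresholdModel",
    "DivisionStats",
    "cell_cycle_threshold",
    "max_trigger_stimulus",
    "fractional_recruitment",
    "fractional_recruitment_no_threshold",
    "interdivision_time",
    "mean_division_rate",
    "max_divisions",
    "division_stats",
]


@dataclass(frozen=True)
class ThresholdModel:
    """Cell-cycle threshold calculus constants.

    Defaults are the published calibration (58.2 complexes/cell × 37.8 h and
    257 complexes/cell × 64 h); :func:`ThresholdModel.from_model` rebuilds
    them from a model's own steady states instead.
    """

    Cs_threshold: float = 2198.0   # complex·h/cell
    max_stimulus: float = 16448.0  # complex·h/cell
    tau_first: float = 37.8        # h, delay to first division at 9 ng/ml
    tau: float = 32.0              # h, dose-independent delay for division counting
    t_full: float = 64.0           # h, complete recruitment at saturating dose

    def __post_init__(self) -> None:
        for name in ("Cs_threshold", "max_stimulus", "tau_first", "tau", "t_full"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.Cs_threshold < self.max_stimulus:
            raise ValueError("Cs_threshold must be below max_stimulus")

    @classmethod
    def from_model(cls, Cs_low: float, Cs_sat: float, tau_first: float = 37.8,
                   tau: float = 32.0, t_full: float = 64.0) -> "ThresholdModel":
        """Threshold constants computed from model steady states: ``Cs_low``
        at the calibration dose (9 ng/ml) and ``Cs_sat`` at saturation."""
        return cls(Cs_threshold=cell_cycle_threshold(Cs_low, tau_first),
                   max_stimulus=max_trigger_stimulus(Cs_sat, t_full),
                   tau_first=tau_first, tau=tau, t_full=t_full)


def cell_cycle_threshold(Cs_ss: float, tau_first: float = 37.8) -> float:
    """Cumulative-stimulus threshold: steady-state surface complexes times
    the delay to first division (complex·h/cell)."""
    if not (Cs_ss > 0 and tau_first > 0):
        raise ValueError("Cs_ss and tau_first must be positive")
    return Cs_ss * tau_first


def max_trigger_stimulus(Cs_sat: float, t_full: float = 64.0) -> float:
    """Stimulus for complete population recruitment: saturating complex
    count times the full-recruitment time (complex·h/cell)."""
    if Cs_sat < 0 or t_full <= 0:
        raise ValueError("Cs_sat must be >= 0 and t_full > 0")
    return Cs_sat * t_full


def fractional_recruitment(Cs_ss: float, t, th: ThresholdModel | None = None):
    """Fraction of the quiescent population recruited into division by time t.

    The net positive cell-cycle momentum ``C_s·t − Cs_threshold`` divided by
    the maximum trigger stimulus, clipped to [0, 1].  Zero whenever the
    cumulative stimulus has not yet crossed the threshold.  Vectorized in t.
    """
    th = th or ThresholdModel()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    frac = np.clip((Cs_ss * t - th.Cs_threshold) / th.max_stimulus, 0.0, 1.0)
    return float(frac) if frac.ndim == 0 else frac


def fractional_recruitment_no_threshold(Cs_ss: float, t,
                                        th: ThresholdModel | None = None):
    """Threshold-free variant: ``C_s·t / max_stimulus`` clipped to [0, 1].

    Always ≥ the thresholded fraction; kept as the comparison model that the
    thresholded formula is validated against.
    """
    th = th or ThresholdModel()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    frac = np.clip(Cs_ss * t / th.max_stimulus, 0.0, 1.0)
    return float(frac) if frac.ndim == 0 else frac


def interdivision_time(total_Cs: float, th: ThresholdModel | None = None) -> float:
    """Minimal time for a dividing cell to complete one division (h):
    threshold divided by its total steady-state surface complexes."""
    th = th or ThresholdModel()
    if total_Cs < 0:
        raise ValueError("total_Cs must be non-negative")
    if total_Cs == 0:
        return math.inf
    return th.Cs_threshold / total_Cs


def mean_division_rate(t_div: float) -> float:
    """Population mean division rate (h⁻¹) from the interdivision time.

    Per-cohort rates spread approximately as a Gaussian from the fastest
    cohort's 1/t_div down to near zero, so the mean is half the maximum:
    ``1/(2·t_div)``.
    """
    if not t_div > 0:
        raise ValueError("t_div must be positive")
    return 1.0 / (2.0 * t_div)


def max_divisions(t: float, tau: float, t_div: float) -> tuple[float, int]:
    """Maximum divisions achievable by time t (h) after a fixed delay tau.

    Returns the real-valued ``(t − tau)/t_div`` together with its floor,
    the integer to compare against CFSE peak counts; 0 for t < tau.
    """
    if t_div <= 0:
        raise ValueError("t_div must be positive")
    if t < tau:
        return 0.0, 0
    n = (t - tau) / t_div
    return n, int(math.floor(n))


@dataclass(frozen=True)
class DivisionStats:
    """One row of the dose → division-kinetics table."""

    dose_ng_ml: float
    total_Cs: float
    t_div: float       # h
    mean_rate: float   # h^-1

    def n_max(self, t: float, tau: float = 32.0) -> float:
        return max_divisions(t, tau, self.t_div)[0]


def division_stats(dose_ng_ml: float, total_Cs: float,
                   th: ThresholdModel | None = None) -> DivisionStats:
    """Interdivision time and mean division rate for one dose."""
    th = th or ThresholdModel()
    t_div = interdivision_time(total_Cs, th)
    return DivisionStats(dose_ng_ml, total_Cs, t_div, mean_division_rate(t_div))
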