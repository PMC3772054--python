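"""Seeded pseudo-experimental datasets mirroring the study's observables.

Three kinds of observations are emulated so that every inference stage can
be exercised and validated without the (unpublished) experimental data:

* fractional-recruitment time series per dose — the thresholded recruitment
  curve plus additive truncated-Gaussian noise on the fraction scale
  (replicate-level noise sd defaults to 0.05, a value chosen to match the
  few-replicate scatter typical of flow-cytometry recruitment estimates;
  the study itself prints no error model),
* maximum CFSE division numbers — integer peak counts, floor of the
  continuous prediction, detection-capped at 8 divisions,
* CFSE-like intensity profiles — mixtures of Gaussian division cohorts on a
  log2-intensity axis with 2-fold (one unit) spacing, undivided cells
  excluded, plus a peak-area estimator that recovers cohort fractions and
  the maximum division number.

All generators are deterministic under a fixed seed, and the ground truth
is independent of the noise parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .proliferation import (
    ThresholdModel,
    fractional_recruitment,
    max_divisions,
)

__all__ = [
    "SyntheticRecruitmentData",
    "CfseProfile",
    "gen_recruitment_obs",
    "gen_max_division_obs",
    "gen_cfse_profile",
    "estimate_cohort_fractions",
    "CFSE_DETECTION_LIMIT",
]

CFSE_DETECTION_LIMIT = 8  # dye dilution limits division tracking to ~8 peaks


@dataclass
class SyntheticRecruitmentData:
    """Noisy recruitment fractions with their generating ground truth."""

    dose_ng_ml: float
    times: np.ndarray          # h
    observed: np.ndarray       # fractions in [0, 1]
    truth: np.ndarray          # noiseless curve
    noise_sd: float
    seed: int
    Cs_ss: float               # steady-state complexes used for the truth


def gen_recruitment_obs(dose_ng_ml: float, times, sd: float, seed: int,
                        th: ThresholdModel | None = None,
                        Cs_ss: float | None = None) -> SyntheticRecruitmentData:
    """Recruitment observations: thresholded truth + N(0, sd), clipped to [0,1].

    ``Cs_ss`` is the steady-state surface complex count for the dose; if not
    given it is computed from the intermediate-affinity model.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty time grid")
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    th = th or ThresholdModel()
    if Cs_ss is None:
        from .intermediate import steady_state_intermediate
        from .units import Dose

        Cs_ss = steady_state_intermediate(Dose(dose_ng_ml)).C_s
    truth = fractional_recruitment(Cs_ss, times, th)
    rng = np.random.default_rng(seed)
    observed = np.clip(truth + rng.normal(0.0, sd, size=times.shape), 0.0, 1.0)
    return SyntheticRecruitmentData(dose_ng_ml, times, observed, truth, sd,
                                    seed, Cs_ss)


def gen_max_division_obs(dose_ng_ml: float, times, th: ThresholdModel,
                         t_div: float, seed: int, jitter: float = 0.0) -> np.ndarray:
    """Integer maximum-division observations at the given times.

    Truth is floor((t − tau)/t_div); with ``jitter`` > 0 each observation is
    shifted by ±1 with that probability (miscounted faint peaks).  Counts
    are capped at the CFSE detection limit and never negative.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < th.tau):
        raise ValueError(f"observation times must be >= tau = {th.tau} h")
    counts = np.array([max_divisions(t, th.tau, t_div)[1] for t in times], dtype=int)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(times.shape) < jitter
        counts = counts + np.where(flip, rng.choice([-1, 1], size=times.shape), 0)
    return np.clip(counts, 0, CFSE_DETECTION_LIMIT)


@dataclass
class CfseProfile:
    """CFSE-like intensity histogram as a Gaussian cohort mixture.

    ``grid`` is a log2-intensity axis; cohort n (n = 1 … n_divisions,
    undivided excluded) is centred one unit (one 2-fold dilution) below its
    predecessor.  ``density`` integrates to 1.
    """

    grid: np.ndarray
    density: np.ndarray
    cohort_means: np.ndarray
    cohort_sd: float
    weights: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)


def gen_cfse_profile(n_divisions: int, weights, cv: float = 0.05,
                     seed: int = 0, x0: float = 10.0,
                     n_grid: int = 2048) -> CfseProfile:
    """Gaussian cohort mixture for cells that divided 1 … n_divisions times.

    ``weights`` are the cohort fractions (must be non-negative and sum
    to 1); ``cv`` is the cohort sd on the log2-intensity axis, i.e. as a
    fraction of the one-unit 2-fold-dilution spacing.  ``x0`` is the log2
    intensity of undivided cells (excluded from the profile).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size != n_divisions:
        raise ValueError("need one weight per division cohort")
    if np.any(weights < 0):
        raise ValueError("cohort weights must be non-negative")
    if not np.isclose(weights.sum(), 1.0, atol=1e-9):
        raise ValueError("cohort weights must sum to 1")
    if not cv > 0:
        raise ValueError("cv must be positive")
    means = x0 - np.arange(1, n_divisions + 1, dtype=float)
    lo, hi = means.min() - 6 * cv - 0.5, means.max() + 6 * cv + 0.5
    grid = np.linspace(lo, hi, n_grid)
    density = np.zeros_like(grid)
    for m, w in zip(means, weights):
        density += w * np.exp(-0.5 * ((grid - m) / cv) ** 2) / (cv * np.sqrt(2 * np.pi))
    density /= np.trapezoid(density, grid)
    return CfseProfile(grid, density, means, cv, weights, seed)


def estimate_cohort_fractions(profile: CfseProfile,
                              smooth_sigma_frac: float = 0.25):
    """Recover cohort weights and the maximum division number from a profile.

    Peaks are detected as local maxima of the density after smoothing with a
    Gaussian of width ``smooth_sigma_frac`` times the cohort sd; each peak's
    cohort fraction is the area between the midpoints to its neighbouring
    peaks, normalized to the total area.  The maximum number of divisions is
    the number of detected peaks (cohorts are one per division, the
    undivided peak being excluded upstream).
    """
    grid, density = profile.grid, profile.density
    dx = grid[1] - grid[0]
    sigma_pts = max(profile.cohort_sd * smooth_sigma_frac / dx, 1.0)
    smoothed = gaussian_filter1d(density, sigma_pts)
    prominence = 0.01 * smoothed.max() if smoothed.max() > 0 else None
    if prominence is None:
        raise ValueError("flat profile: no peaks detectable")
    peaks, _ = find_peaks(smoothed, prominence=prominence)
    if peaks.size == 0:
        raise ValueError("flat profile: no peaks detectable")
    # integration boundaries: midpoints between adjacent peak positions
    bounds = np.concatenate(([0], (peaks[:-1] + peaks[1:]) // 2, [grid.size - 1]))
    areas = np.array([np.trapezoid(density[a:b + 1], grid[a:b + 1])
                      for a, b in zip(bounds[:-1], bounds[1:])])
    weights = areas / areas.sum()
    # peaks are found in ascending grid order = descending division number
    return weights[::-1], int(peaks.size)
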