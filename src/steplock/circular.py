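"""Relative phase angles and the circular-range uniformity test.

The relative phase angle (rPA) of a footfall is its timing within the
surrounding beat interval, expressed in degrees on (-180, +180]: negative
means the step fell before the nearest beat, positive after it.  A window of
tightly concentrated rPA indicates phase locking; rPA spread over the circle
indicates unlocking.  Concentration is tested with the circular range — 360
degrees minus the largest angular gap between sorted observations — whose
exact null distribution under circular uniformity has a closed-form tail sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io_model import EventSeries, TrialDataError


@dataclass(frozen=True)
class PhaseSeries:
    """rPA observations in degrees on (-180, +180], stamped at step times."""

    times: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.angles, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and angles must be 1-d arrays of equal length")
        if a.size and (a.min() <= -180.0 or a.max() > 180.0):
            raise ValueError("angles must lie in (-180, +180]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "angles", a)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PhaseDropReport:
    """Steps that had no surrounding beat interval and were dropped."""

    dropped_indices: np.ndarray

    @property
    def n_dropped(self) -> int:
        return int(np.asarray(self.dropped_indices).size)


@dataclass(frozen=True)
class UniformityTestResult:
    """Circular-range test of uniformity (H0: uniform, i.e. high fluctuation)."""

    statistic: float  # circular range, degrees in [0, 360)
    p_value: float
    n: int
    alpha: float
    reject: bool


def relative_phase_angles(
    steps: EventSeries, beats: EventSeries
) -> tuple[PhaseSeries, PhaseDropReport]:
    """Compute rPA for every step bracketed by two beats.

    For a step with prior beat B_j and next beat B_{j+1} the raw phase is
    ``360 * (step - B_j) / (B_{j+1} - B_j)`` in [0, 360), re-expressed on
    (-180, +180] by subtracting 360 when above 180 so that a step just before
    a beat gets a small negative angle.  Steps before the first beat or at or
    after the last beat are dropped and reported.
    """
    bt = beats.times
    if bt.size < 2:
        raise TrialDataError("need at least two beats to form a beat interval")
    st = steps.times
    j = np.searchsorted(bt, st, side="right") - 1
    valid = (j >= 0) & (j < bt.size - 1)
    jv = j[valid]
    ibi = bt[jv + 1] - bt[jv]
    if np.any(ibi <= 0):
        raise TrialDataError("zero-length beat interval")
    raw = 360.0 * (st[valid] - bt[jv]) / ibi
    angles = np.where(raw > 180.0, raw - 360.0, raw)
    return (
        PhaseSeries(times=st[valid], angles=angles),
        PhaseDropReport(np.flatnonzero(~valid)),
    )


def circular_mean_and_R(angles: np.ndarray) -> tuple[float, float]:
    """Circular mean direction (degrees) and mean resultant length R.

    When R is numerically zero (perfect cancellation) the mean direction is
    undefined and reported as NaN.
    """
    a = np.deg2rad(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one angle")
    c, s = np.mean(np.cos(a)), np.mean(np.sin(a))
    r = float(np.hypot(c, s))
    if r < 1e-12:
        return float("nan"), r
    mean = float(np.rad2deg(np.arctan2(s, c)))
    if mean <= -180.0:  # arctan2 can return -pi exactly
        mean += 360.0
    return mean, r


def circular_range(angles: np.ndarray) -> float:
    """Circular range in degrees: 360 minus the largest gap between angles."""
    a = np.asarray(angles, dtype=float)
    if a.size < 2:
        raise ValueError("circular range needs at least 2 angles")
    a = np.sort(np.mod(a, 360.0))
    gaps = np.diff(a)
    wrap = a[0] + 360.0 - a[-1]
    return float(360.0 - max(gaps.max() if gaps.size else 0.0, wrap))


def circular_range_pvalue(range_deg, n: int):
    """Exact null probability P(circular range <= w) under uniformity.

    With t = 1 - w/360 the tail sum is
    ``p = sum_{k>=1} (-1)^(k-1) C(n, k) (1 - k t)_+^(n-1)``;
    terms vanish once ``1 - k t <= 0`` or ``k > n``.  Small p (tight
    concentration) is evidence against uniformity.  Vectorised over
    ``range_deg``.
    """
    if n < 2:
        raise ValueError("uniformity test needs n >= 2")
    w = np.asarray(range_deg, dtype=float)
    scalar = w.ndim == 0
    w = np.atleast_1d(w)
    if np.any((w < 0) | (w > 360.0)):
        raise ValueError("circular range must lie in [0, 360]")
    t = 1.0 - w / 360.0
    k = np.arange(1, n + 1, dtype=float)
    # log C(n, k), computed stably; n is small in practice but keep it safe
    log_comb = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    )
    base = np.clip(1.0 - np.outer(t, k), 0.0, None)
    with np.errstate(divide="ignore"):
        terms = np.where(
            base > 0,
            np.exp(log_comb[None, :] + (n - 1) * np.log(np.where(base > 0, base, 1.0))),
            0.0,
        )
    signs = np.where(np.arange(1, n + 1) % 2 == 1, 1.0, -1.0)
    p = np.clip((terms * signs[None, :]).sum(axis=1), 0.0, 1.0)
    return float(p[0]) if scalar else p


def circular_uniformity_test(
    angles: np.ndarray, alpha: float = 0.05
) -> UniformityTestResult:
    """Test H0: circular uniformity against concentration on an arc.

    Rejection (p < alpha) indicates low fluctuation — evidence of phase
    locking.  No modal direction is assumed or estimated.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    a = np.asarray(angles, dtype=float)
    if a.size < 2:
        raise ValueError("uniformity test needs at least 2 angles")
    w = circular_range(a)
    p = float(circular_range_pvalue(w, int(a.size)))
    return UniformityTestResult(
        statistic=w, p_value=p, n=int(a.size), alpha=alpha, reject=p < alpha
    )
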