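"""Inter-step intervals, outlier removal, truncation and window partitioning.

The inter-step interval delta_j = Step_{j+1} - Step_j is stamped at the time
of its initiating step, t_j = Step_j.  Cleaning removes observations outside
median +/- 3 sd in a single pass, trials are truncated to their nominal
length, and the remaining observations are partitioned into consecutive
fixed-length half-open windows [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .io_model import EventSeries, TrialDataError


@dataclass(frozen=True)
class IntervalSeries:
    """Inter-step intervals delta_j (seconds) stamped at times t_j = Step_j."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class OutlierReport:
    """Which observations the median +/- k sd rule removed, and its bounds."""

    removed_indices: np.ndarray
    lower: float
    upper: float

    @property
    def n_removed(self) -> int:
        return int(np.asarray(self.removed_indices).size)


@dataclass(frozen=True)
class Window:
    """One window of a partitioned series (index is 1-based)."""

    index: int
    times: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return int(np.asarray(self.times).size)


@dataclass(frozen=True)
class WindowedSeries:
    """A time-stamped series partitioned into consecutive equal windows."""

    window_length: float
    windows: tuple[Window, ...]

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(w) for w in self.windows], dtype=int)

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenate all windows back into (times, values)."""
        if not self.windows:
            return np.empty(0), np.empty(0)
        times = np.concatenate([w.times for w in self.windows])
        values = np.concatenate([w.values for w in self.windows])
        return times, values


def _observations(series) -> tuple[np.ndarray, np.ndarray, Callable]:
    """Extract (times, values, rebuild) from a time-stamped series.

    Accepts an ``(times, values)`` tuple, an :class:`IntervalSeries`, or any
    dataclass exposing ``times`` plus ``values``/``angles``.
    """
    if isinstance(series, tuple):
        t, v = series
        return np.asarray(t, float), np.asarray(v, float), lambda a, b: (a, b)
    for attr in ("values", "angles"):
        if hasattr(series, attr):
            cls = type(series)

            def rebuild(a, b, _cls=cls, _attr=attr):
                return _cls(times=a, **{_attr: b})

            return np.asarray(series.times, float), np.asarray(
                getattr(series, attr), float
            ), rebuild
    raise TypeError(f"not a time-stamped series: {type(series).__name__}")


def inter_step_intervals(steps: EventSeries) -> IntervalSeries:
    """Derive the J-1 inter-step intervals from J step times."""
    t = steps.times
    if t.size < 2:
        raise TrialDataError("need at least 2 steps to form an inter-step interval")
    return IntervalSeries(times=t[:-1], values=np.diff(t))


def remove_outliers(
    series: IntervalSeries, k: float = 3.0, ddof: int = 1
) -> tuple[IntervalSeries, OutlierReport]:
    """Single-pass removal of observations outside median +/- k sd.

    The median and standard deviation are computed once on the raw input
    values (``ddof=1``: sample sd).  With a degenerate sd (constant series or
    a single value) nothing is removed.
    """
    if len(series) == 0:
        raise TrialDataError("cannot clean an empty interval series")
    v = series.values
    med = float(np.median(v))
    sd = float(np.std(v, ddof=ddof)) if v.size > ddof else 0.0
    if not np.isfinite(sd):
        sd = 0.0
    lower, upper = med - k * sd, med + k * sd
    keep = (v >= lower) & (v <= upper)
    report = OutlierReport(np.flatnonzero(~keep), lower, upper)
    return IntervalSeries(series.times[keep], v[keep]), report


def truncate(series, limit: float):
    """Drop every observation at or after ``limit`` seconds (half-open)."""
    if limit <= 0:
        raise ValueError("limit must be positive")
    times, values, rebuild = _observations(series)
    keep = times < limit
    return rebuild(times[keep], values[keep])


def partition_windows(series, window_length: float, total_length: float) -> WindowedSeries:
    """Partition a time-stamped series into equal half-open windows.

    ``window_length`` must divide ``total_length`` exactly; an observation at
    time t falls in window ``floor(t / window_length) + 1``.  Empty windows
    are retained so that every series over [0, total_length) yields the same
    window count.
    """
    if window_length <= 0 or total_length <= 0:
        raise ValueError("window_length and total_length must be positive")
    ratio = total_length / window_length
    n = int(round(ratio))
    if n < 1 or abs(ratio - n) > 1e-9:
        raise ValueError(
            f"window_length {window_length} does not divide total_length "
            f"{total_length} exactly"
        )
    times, values, _ = _observations(series)
    if times.size and (times.min() < 0 or times.max() >= total_length):
        raise ValueError(
            "observations outside [0, total_length); truncate the series first"
        )
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    idx = np.minimum(np.floor(times / window_length).astype(int) + 1, n)
    windows = tuple(
        Window(k, times[idx == k], values[idx == k]) for k in range(1, n + 1)
    )
    return WindowedSeries(window_length=float(window_length), windows=windows)
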