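"""Locked/unlocked window labelling.

Each 20-second window of a trial receives two labels that are then combined:

* a fluctuation label from the circular uniformity test (rejection of
  uniformity = concentrated rPA = locked evidence), and
* a trend label from a window-specific slope test: a linear mixed model
  ``rPA ~ 1 + s`` with a random intercept and slope per window (s = seconds
  since window start) is fitted per trial by REML, and each window's BLUP
  deviation from the overall slope is tested against zero with a
  standard-normal reference on BLUP / prediction SE.  A significant
  deviation marks the window as drifting (unlocked evidence).

The final label is locked only when both evaluations say locked; windows
with too few observations are unevaluable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

from .circular import circular_uniformity_test, relative_phase_angles
from .config import PipelineConfig
from .io_model import Trial, TrialDataError
from .preprocess import WindowedSeries, partition_windows, truncate

LOCKED = "locked"
UNLOCKED = "unlocked"
UNEVALUABLE = "unevaluable"

_LABELS = (LOCKED, UNLOCKED, UNEVALUABLE)

#: random-slope variance (deg/s)^2 below which the REML fit is treated as
#: sitting on the boundary: no window deviates from the common trend.
_BOUNDARY_VAR = 1e-8


@dataclass(frozen=True)
class WindowSlope:
    """Slope-test record for one window."""

    window_index: int
    n_obs: int
    deviation: float  # BLUP of the window's slope deviation, deg/s
    se: float
    statistic: float
    p_value: float
    label: str


@dataclass(frozen=True)
class SlopeTestResult:
    """Per-trial slope test: overall trend plus per-window deviations."""

    overall_slope: float
    windows: tuple[WindowSlope, ...]
    boundary: bool

    def labels(self) -> list[str]:
        return [w.label for w in self.windows]


@dataclass(frozen=True)
class WindowLabel:
    """Combined classification record for one window."""

    window_index: int
    circ_label: str
    slope_label: str
    final_label: str
    circ_p: float
    slope_p: float


def combine_labels(circ: str, slope: str) -> str:
    """Combine the two evaluations: locked only if both are locked.

    Either evaluation flagging unlocked makes the window unlocked; an
    unevaluable component propagates.
    """
    for lab in (circ, slope):
        if lab not in _LABELS:
            raise ValueError(f"unknown label {lab!r}")
    if UNEVALUABLE in (circ, slope):
        return UNEVALUABLE
    if circ == LOCKED and slope == LOCKED:
        return LOCKED
    return UNLOCKED


def window_slope_test(
    windowed_rpa: WindowedSeries,
    alpha: float = 0.05,
    min_obs: int = 8,
    bonferroni: bool = False,
) -> SlopeTestResult:
    """Test each window's rPA slope deviation from the trial's overall slope.

    Windows with fewer than ``min_obs`` observations are excluded from the
    model and labelled unevaluable.  When the REML estimate of the random
    slope variance is at the zero boundary, no window can deviate from the
    common trend: all evaluable windows are labelled locked with a warning.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    wl = windowed_rpa.window_length
    rows = []
    evaluable = []
    for w in windowed_rpa.windows:
        if len(w) >= min_obs:
            evaluable.append(w.index)
            s = w.times - (w.index - 1) * wl
            rows.append(
                pd.DataFrame({"rpa": w.values, "s": s, "window": w.index})
            )
    if len(evaluable) < 2:
        raise TrialDataError(
            f"slope test needs at least 2 evaluable windows, got {len(evaluable)}"
        )
    data = pd.concat(rows, ignore_index=True)

    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "rpa ~ s", data, groups=data["window"], re_formula="~s"
        )
        # small-sample REML surfaces often trip the first optimizer's
        # convergence flag at a perfectly usable optimum; try a few
        for method in ("lbfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=True, method=method, maxiter=500)
            except Exception:
                continue
            if not np.all(np.isfinite(cand.fe_params)) or not np.all(
                np.isfinite(np.asarray(cand.cov_re))
            ):
                continue
            if res is None or cand.llf > res.llf + 1e-9 or cand.converged:
                res = cand
            if cand.converged:
                break
    if res is None:
        raise TrialDataError("slope-model REML fit failed")
    if not res.converged:
        warnings.warn(
            "slope-model REML optimizer did not flag convergence; using the "
            "best finite optimum found",
            stacklevel=2,
        )

    slope_var = float(np.asarray(res.cov_re)[1, 1])
    boundary = slope_var <= _BOUNDARY_VAR
    if boundary:
        warnings.warn(
            "random-slope variance at boundary zero: all windows share the "
            "overall trend and are labelled locked by the slope test",
            stacklevel=2,
        )

    n_tests = len(evaluable) if bonferroni else 1
    # BLUPs and their prediction covariances computed directly from the
    # plugged-in REML variance components: for window k with random-effect
    # design Z_k (= fixed design X_k here) and V_k = Z_k G Z_k' + s2 I,
    #   b_hat_k = G Z_k' V_k^{-1} (y_k - X_k beta_hat)
    #   Cov(b_hat_k - b_k) = G - G Z_k' V_k^{-1} Z_k G
    #                        + (G Z_k' V_k^{-1} X_k) A (G Z_k' V_k^{-1} X_k)'
    # with A = (X' V^{-1} X)^{-1}.  The last term carries the uncertainty of
    # the overall intercept/slope, which with only ~9 windows is far from
    # negligible; dropping it (the purely conditional covariance) overstates
    # the evidence that a window deviates from the overall trend.  The
    # expressions stay well-defined when G is singular (boundary fits).
    G = np.asarray(res.cov_re, dtype=float)
    s2 = float(res.scale)
    b0, b1 = float(res.fe_params.iloc[0]), float(res.fe_params["s"])
    per_window: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    xtvix = np.zeros((2, 2))
    for w in windowed_rpa.windows:
        if w.index not in evaluable or boundary:
            continue
        s = w.times - (w.index - 1) * wl
        Z = np.column_stack([np.ones(len(w)), s])
        V = Z @ G @ Z.T + s2 * np.eye(len(w))
        Vi_Z = np.linalg.solve(V, Z)
        per_window[w.index] = (s, Z, Vi_Z)
        xtvix += Z.T @ Vi_Z
    A = np.linalg.inv(xtvix) if per_window else None

    records: list[WindowSlope] = []
    for w in windowed_rpa.windows:
        if w.index not in evaluable:
            records.append(
                WindowSlope(w.index, len(w), np.nan, np.nan, np.nan, np.nan, UNEVALUABLE)
            )
            continue
        if boundary:
            records.append(
                WindowSlope(w.index, len(w), 0.0, 0.0, 0.0, 1.0, LOCKED)
            )
            continue
        s, Z, Vi_Z = per_window[w.index]
        resid = w.values - (b0 + b1 * s)
        blup = float((G @ (Vi_Z.T @ resid))[1])  # V symmetric: Z'V^{-1} = (V^{-1}Z)'
        M = G @ Z.T @ Vi_Z  # = G Z' V^{-1} X since X_k = Z_k
        cond = G - M @ G + M @ A @ M.T
        var = max(0.0, float(cond[1, 1]))
        se = float(np.sqrt(var))
        if se <= 1e-12 or not np.isfinite(se):
            z, p = 0.0, 1.0
        else:
            z = blup / se
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * n_tests)
        label = UNLOCKED if p < alpha else LOCKED
        records.append(WindowSlope(w.index, len(w), blup, se, z, p, label))

    return SlopeTestResult(
        overall_slope=float(res.fe_params["s"]),
        windows=tuple(records),
        boundary=boundary,
    )


def classify_trial(
    trial: Trial, config: PipelineConfig | None = None
) -> list[WindowLabel]:
    """Run the full per-trial labelling pipeline.

    rPA computation -> truncation to the nominal duration -> window
    partitioning -> per-window circular uniformity test and trial-level
    slope test -> combined final labels.  Returns one :class:`WindowLabel`
    per window (nine for the 180 s / 20 s defaults).
    """
    cfg = config or PipelineConfig()
    phases, _ = relative_phase_angles(trial.steps, trial.beats)
    phases = truncate(phases, cfg.trial_duration_s)
    windowed = partition_windows(phases, cfg.window_length_s, cfg.trial_duration_s)

    min_obs = max(2, cfg.min_obs_per_window)
    circ_labels: dict[int, tuple[str, float]] = {}
    for w in windowed.windows:
        if len(w) < min_obs:
            circ_labels[w.index] = (UNEVALUABLE, np.nan)
        else:
            test = circular_uniformity_test(w.values, alpha=cfg.alpha_circ)
            circ_labels[w.index] = (LOCKED if test.reject else UNLOCKED, test.p_value)

    n_evaluable = sum(1 for w in windowed.windows if len(w) >= min_obs)
    if n_evaluable >= 2:
        slope = window_slope_test(
            windowed,
            alpha=cfg.alpha_slope,
            min_obs=min_obs,
            bonferroni=cfg.bonferroni_slope,
        )
        slope_by_window = {w.window_index: (w.label, w.p_value) for w in slope.windows}
    else:
        slope_by_window = {
            w.index: (UNEVALUABLE, np.nan) for w in windowed.windows
        }

    labels = []
    for w in windowed.windows:
        circ_lab, circ_p = circ_labels[w.index]
        slope_lab, slope_p = slope_by_window[w.index]
        labels.append(
            WindowLabel(
                window_index=w.index,
                circ_label=circ_lab,
                slope_label=slope_lab,
                final_label=combine_labels(circ_lab, slope_lab),
                circ_p=circ_p,
                slope_p=slope_p,
            )
        )
    return labels
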