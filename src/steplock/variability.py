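"""Inter-step-interval variability: per-window SDs and the log-SD mixed model.

Each evaluable window contributes one standard deviation S of its inter-step
intervals (population denominator J, as the repeated outcome is a descriptive
within-window statistic, not an estimator of a common variance).  log S is
modelled as a linear function of the design factors — tempo (reference 0%),
stimulus (reference metronome), the rescaled window ordinal (window/10, for
better conditioning) and the lock label (reference locked) — with chosen
two-way interactions and a subject-level random intercept, fitted by REML.
Fixed-effect p-values use the normal approximation on estimate/SE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .classifier import LOCKED, UNEVALUABLE, UNLOCKED, WindowLabel
from .io_model import TrialDataError, TrialMeta, tempo_label
from .preprocess import WindowedSeries

#: tempo factor levels in coefficient-table order (reference level "0" omitted)
TEMPO_COEF_ORDER: tuple[str, ...] = ("n12", "n4", "n8", "p12", "p4", "p8")

#: canonical interaction blocks the mean structure may contain
INTERACTION_BLOCKS: tuple[tuple[str, str], ...] = (
    ("tempi", "stimuli"),
    ("tempi", "lock"),
    ("tempi", "window"),
    ("stimuli", "lock"),
    ("stimuli", "window"),
    ("lock", "window"),
)

#: default mean structure: main effects plus the two interaction blocks of
#: the final reduced model (tempo x stimulus and tempo x lock)
DEFAULT_INTERACTIONS: tuple[tuple[str, str], ...] = (
    ("tempi", "stimuli"),
    ("tempi", "lock"),
)


@dataclass(frozen=True)
class VariabilityRecord:
    """Per-window SD of the inter-step interval plus its design factors."""

    subject_id: str
    stimulus: str
    tempo_offset: int
    window_index: int
    lock_label: str
    sd_isi: float
    n_steps: int

    def __post_init__(self) -> None:
        if self.sd_isi < 0:
            raise ValueError("sd_isi must be non-negative")
        if self.lock_label not in (LOCKED, UNLOCKED):
            raise ValueError("lock_label must be 'locked' or 'unlocked'")
        if self.window_index < 1:
            raise ValueError("window_index is 1-based")

    @property
    def window_rescaled(self) -> float:
        return self.window_index / 10.0


@dataclass(frozen=True)
class ModelFitResult:
    """Fixed-effect table plus variance components of the log-SD model."""

    table: pd.DataFrame  # columns: Parameter, Estimate, Std. error, t, p-value
    random_intercept_var: float
    residual_var: float
    loglike: float
    interactions: tuple[tuple[str, str], ...]
    reml: bool

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.table["Parameter"], self.table["Estimate"]))

    @property
    def se(self) -> dict[str, float]:
        return dict(zip(self.table["Parameter"], self.table["Std. error"]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.4f")


def window_sd(values: Sequence[float]) -> float:
    """Population-denominator standard deviation of one window's intervals.

    Divides by the window's step count J, not J-1, so the statistic is the
    exact root-mean-square deviation of the observed intervals.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise TrialDataError("window SD needs at least 2 intervals")
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def merge_labels(
    isi_windows: WindowedSeries,
    labels: Sequence[WindowLabel],
    meta: TrialMeta,
    label_window_length: float | None = None,
) -> tuple[list[VariabilityRecord], list[int]]:
    """Attach final lock labels to per-window interval SDs.

    Both inputs must share the window partition.  Windows that are
    unevaluable on either side (label unevaluable, or fewer than 2 intervals)
    are dropped; their indices are returned as the second element.
    """
    if label_window_length is not None and not math.isclose(
        label_window_length, isi_windows.window_length
    ):
        raise ValueError(
            f"window_length mismatch: labels use {label_window_length}, "
            f"intervals use {isi_windows.window_length}"
        )
    if len(labels) != isi_windows.n_windows:
        raise ValueError(
            f"label count {len(labels)} != window count {isi_windows.n_windows}"
        )
    by_index = {lab.window_index: lab for lab in labels}
    if sorted(by_index) != [w.index for w in isi_windows.windows]:
        raise ValueError("label window indices do not match the partition")

    records: list[VariabilityRecord] = []
    dropped: list[int] = []
    for w in isi_windows.windows:
        lab = by_index[w.index]
        if lab.final_label == UNEVALUABLE or len(w) < 2:
            dropped.append(w.index)
            continue
        records.append(
            VariabilityRecord(
                subject_id=meta.subject_id,
                stimulus=meta.stimulus,
                tempo_offset=meta.tempo_offset,
                window_index=w.index,
                lock_label=lab.final_label,
                sd_isi=window_sd(w.values),
                n_steps=len(w),
            )
        )
    return records, dropped


def records_frame(records: Iterable[VariabilityRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "stimulus": r.stimulus,
            "tempo_offset": r.tempo_offset,
            "tempo_lab": tempo_label(r.tempo_offset),
            "window_index": r.window_index,
            "window_resc": r.window_rescaled,
            "lock_label": r.lock_label,
            "sd_isi": r.sd_isi,
            "n_steps": r.n_steps,
        }
        for r in records
    ]
    if not rows:
        raise ValueError("no variability records supplied")
    return pd.DataFrame(rows)


def _canon_block(block: tuple[str, str]) -> tuple[str, str]:
    pair = frozenset(block)
    for b in INTERACTION_BLOCKS:
        if frozenset(b) == pair:
            return b
    raise ValueError(f"unknown interaction block {block!r}")


def design_matrix(
    frame: pd.DataFrame,
    interactions: Sequence[tuple[str, str]] = DEFAULT_INTERACTIONS,
    drop_empty: bool = True,
) -> pd.DataFrame:
    """Fixed-effects design matrix in the coefficient-table naming dialect.

    Reference levels: tempo 0, stimulus metronome, lock locked.  Interaction
    columns are elementwise products of the main-effect columns.  All-zero
    columns (absent factor levels) are dropped with a warning when
    ``drop_empty`` is set.
    """
    main: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(frame))}
    tempo_cols = {}
    for lbl in TEMPO_COEF_ORDER:
        col = (frame["tempo_lab"] == lbl).to_numpy(float)
        tempo_cols[f"Tempi: {lbl}"] = col
    main.update(tempo_cols)
    music = (frame["stimulus"] == "music").to_numpy(float)
    unlocked = (frame["lock_label"] == UNLOCKED).to_numpy(float)
    wresc = frame["window_resc"].to_numpy(float)
    main["Stimuli: music"] = music
    main["Window_lab_resc"] = wresc
    main["Lock_lab: unlocked"] = unlocked

    X = dict(main)
    seen = set()
    for block in interactions:
        block = _canon_block(block)
        if block in seen:
            continue
        seen.add(block)
        for name, col in interaction_columns(block, tempo_cols, music, unlocked, wresc):
            X[name] = col

    out = pd.DataFrame(X, index=frame.index)
    if drop_empty:
        empty = [c for c in out.columns if c != "(Intercept)" and not out[c].any()]
        if empty:
            warnings.warn(
                f"dropping design column(s) with no observations: {empty}",
                stacklevel=2,
            )
            out = out.drop(columns=empty)
    return out


def interaction_columns(block, tempo_cols, music, unlocked, wresc):
    """Yield (name, column) pairs for one canonical interaction block."""
    if block == ("tempi", "stimuli"):
        for name, col in tempo_cols.items():
            yield f"{name} * Stimuli: music", col * music
    elif block == ("tempi", "lock"):
        for name, col in tempo_cols.items():
            yield f"{name} * Lock_lab: unlocked", col * unlocked
    elif block == ("tempi", "window"):
        for name, col in tempo_cols.items():
            yield f"{name} * Window_lab_resc", col * wresc
    elif block == ("stimuli", "lock"):
        yield "Stimuli: music * Lock_lab: unlocked", music * unlocked
    elif block == ("stimuli", "window"):
        yield "Stimuli: music * Window_lab_resc", music * wresc
    elif block == ("lock", "window"):
        yield "Window_lab_resc * Lock_lab: unlocked", wresc * unlocked
    else:  # pragma: no cover
        raise ValueError(f"unknown block {block!r}")


def _block_columns(block: tuple[str, str], X: pd.DataFrame) -> list[str]:
    tokens = {
        "tempi": "Tempi: ",
        "stimuli": "Stimuli: music",
        "lock": "Lock_lab: unlocked",
        "window": "Window_lab_resc",
    }
    a, b = block
    return [
        c
        for c in X.columns
        if " * " in c and tokens[a] in c and tokens[b] in c
    ]


def fit_variability_model(
    records: Iterable[VariabilityRecord] | pd.DataFrame,
    interactions: Sequence[tuple[str, str]] = DEFAULT_INTERACTIONS,
    reml: bool = True,
    log_base: float = math.e,
) -> ModelFitResult:
    """Fit the log-SD linear mixed model with a subject random intercept.

    ``log(S)`` (natural log by default) is regressed on tempo, stimulus,
    rescaled window and lock label plus the requested interaction blocks;
    subjects contribute a random intercept.  Records with S = 0 are rejected
    — apply a positive floor or exclude them before fitting.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if (frame["sd_isi"] <= 0).any():
        n_bad = int((frame["sd_isi"] <= 0).sum())
        raise TrialDataError(
            f"{n_bad} record(s) have sd_isi <= 0; log is undefined — apply a "
            "positive floor or exclude those records before fitting"
        )
    if frame["subject_id"].nunique() < 2:
        raise TrialDataError("need at least 2 subjects for a random intercept")
    if frame["lock_label"].nunique() < 2:
        raise TrialDataError("need both lock labels present to estimate the lock effect")
    present = set(frame["tempo_lab"])
    missing = [l for l in ("0",) + TEMPO_COEF_ORDER if l not in present]
    if missing:
        warnings.warn(f"tempo level(s) missing from data: {missing}", stacklevel=2)

    y = np.log(frame["sd_isi"].to_numpy(float)) / math.log(log_base)
    X = design_matrix(frame, interactions)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=frame["subject_id"])
        for method in ("lbfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=reml, method=method, maxiter=500)
            except Exception:
                continue
            if not np.all(np.isfinite(cand.fe_params)):
                continue
            if res is None or cand.llf > res.llf + 1e-9 or cand.converged:
                res = cand
            if cand.converged:
                break
    if res is None:
        raise TrialDataError("variability-model fit failed")
    if not res.converged:
        warnings.warn(
            "variability-model optimizer did not flag convergence; using the "
            "best finite optimum found",
            stacklevel=2,
        )

    est = res.fe_params
    se = res.bse_fe
    t = est / se
    p = 2.0 * stats.norm.sf(np.abs(t))
    table = pd.DataFrame(
        {
            "Parameter": list(X.columns),
            "Estimate": est.to_numpy(),
            "Std. error": se.to_numpy(),
            "t": t.to_numpy(),
            "p-value": p,
        }
    )
    return ModelFitResult(
        table=table,
        random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
        residual_var=float(res.scale),
        loglike=float(res.llf),
        interactions=tuple(_canon_block(b) for b in interactions),
        reml=reml,
    )


def model_reduction(
    records: Iterable[VariabilityRecord] | pd.DataFrame,
    full_interactions: Sequence[tuple[str, str]] = INTERACTION_BLOCKS[:5],
    threshold: float = 0.05,
) -> ModelFitResult:
    """Backward elimination over interaction blocks of the mean structure.

    Main effects are always retained.  At each step every remaining block is
    tested by a likelihood-ratio test between ML fits with and without it;
    the least significant block is dropped while its p-value exceeds
    ``threshold``.  The final model is refitted by REML.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_frame(records)
    current = [_canon_block(b) for b in full_interactions]

    def ml_fit(blocks):
        return fit_variability_model(frame, interactions=blocks, reml=False)

    while current:
        full = ml_fit(current)
        X_full = design_matrix(frame, current)
        pvals = []
        for block in current:
            reduced = [b for b in current if b != block]
            red = ml_fit(reduced)
            df = len(_block_columns(block, X_full))
            lr = max(0.0, 2.0 * (full.loglike - red.loglike))
            pvals.append((float(stats.chi2.sf(lr, df)), block))
        worst_p, worst_block = max(pvals, key=lambda x: x[0])
        if worst_p > threshold:
            current = [b for b in current if b != worst_block]
        else:
            break

    return fit_variability_model(frame, interactions=current, reml=True)
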