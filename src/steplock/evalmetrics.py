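"""Confusion-matrix verification and inter-rater agreement.

The positive class is "locked": a true positive is a window labelled locked
whose ground truth is locked.  This orientation matters — precision and
recall flip if the opposite convention is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .classifier import LOCKED, UNEVALUABLE, UNLOCKED


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with locked as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy, precision and recall; NaN flags an undefined ratio."""

    accuracy: float
    precision: float
    recall: float


def confusion(
    labels: Sequence[str], truth: Sequence[str]
) -> tuple[ConfusionCounts, list[int]]:
    """Count TP/TN/FP/FN of predicted labels against ground truth.

    ``truth`` may be a :class:`~steplock.synth.GroundTruth` or any aligned
    sequence of locked/unlocked labels.  Unevaluable predictions are excluded;
    their positions are returned as the second element.
    """
    truth_labels = list(getattr(truth, "labels", truth))
    labels = list(labels)
    if len(labels) != len(truth_labels):
        raise ValueError(
            f"length mismatch: {len(labels)} labels vs {len(truth_labels)} truths"
        )
    tp = tn = fp = fn = 0
    excluded: list[int] = []
    for i, (lab, tru) in enumerate(zip(labels, truth_labels)):
        if lab == UNEVALUABLE or tru == UNEVALUABLE:
            excluded.append(i)
            continue
        if lab not in (LOCKED, UNLOCKED) or tru not in (LOCKED, UNLOCKED):
            raise ValueError(f"unknown label pair ({lab!r}, {tru!r}) at position {i}")
        if lab == LOCKED:
            if tru == LOCKED:
                tp += 1
            else:
                fp += 1
        else:
            if tru == UNLOCKED:
                tn += 1
            else:
                fn += 1
    if tp + tn + fp + fn == 0:
        raise ValueError("no evaluable label/truth pairs")
    return ConfusionCounts(tp, tn, fp, fn), excluded


def confusion_metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """Accuracy (TP+TN)/Total, precision TP/(TP+FP), recall TP/(TP+FN).

    A zero denominator yields NaN for that metric rather than an exception.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return ClassificationMetrics(
        accuracy=ratio(counts.tp + counts.tn, counts.total),
        precision=ratio(counts.tp, counts.tp + counts.fp),
        recall=ratio(counts.tp, counts.tp + counts.fn),
    )


#: agreement bands for interpreting kappa (annotation only)
KAPPA_BANDS = ((0.80, "strong"), (0.60, "moderate"), (0.0, "weak"))


def kappa_band(kappa: float) -> str:
    for lo, name in KAPPA_BANDS:
        if kappa >= lo:
            return name
    return "poor"


def cohens_kappa(rater_a: Sequence[str], rater_b: Sequence[str]) -> float:
    """Chance-corrected agreement between two binary label streams.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    raters' marginal label proportions.  When both raters are constant and
    identical (p_e = 1) kappa is undefined and NaN is returned.
    """
    a, b = list(rater_a), list(rater_b)
    if len(a) != len(b):
        raise ValueError("label streams must be aligned")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 paired labels")
    classes = sorted(set(a) | set(b))
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = sum(
        (a.count(c) / n) * (b.count(c) / n) for c in classes
    )
    if abs(1.0 - p_e) < 1e-12:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)
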