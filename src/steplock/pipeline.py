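"""End-to-end orchestration: classify trials, merge, and model variability."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .classifier import classify_trial
from .config import PipelineConfig
from .io_model import Trial, TrialDataError
from .preprocess import inter_step_intervals, partition_windows, remove_outliers, truncate
from .variability import (
    ModelFitResult,
    VariabilityRecord,
    fit_variability_model,
    merge_labels,
    model_reduction,
    records_frame,
)

log = logging.getLogger("steplock")


@dataclass
class PipelineResult:
    """Everything one batch run produces."""

    labels: pd.DataFrame
    records: list[VariabilityRecord]
    fit: ModelFitResult | None
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def records_frame(self) -> pd.DataFrame:
        return records_frame(self.records)


def process_trial(
    trial: Trial, config: PipelineConfig
) -> tuple[list, list[VariabilityRecord]]:
    """Label one trial's windows and build its variability records."""
    labels = classify_trial(trial, config)

    isi = inter_step_intervals(trial.steps)
    isi, report = remove_outliers(isi, k=config.outlier_k)
    if report.n_removed:
        log.info(
            "%s %s %+d: removed %d interval outlier(s) outside [%.4f, %.4f]",
            trial.meta.subject_id,
            trial.meta.stimulus,
            trial.meta.tempo_offset,
            report.n_removed,
            report.lower,
            report.upper,
        )
    isi = truncate(isi, config.trial_duration_s)
    windowed = partition_windows(isi, config.window_length_s, config.trial_duration_s)
    records, dropped = merge_labels(
        windowed, labels, trial.meta, label_window_length=config.window_length_s
    )
    if dropped:
        log.info(
            "%s %s %+d: window(s) %s unevaluable, dropped from variability records",
            trial.meta.subject_id,
            trial.meta.stimulus,
            trial.meta.tempo_offset,
            dropped,
        )
    return labels, records


def run_pipeline(
    trials: Sequence[Trial],
    config: PipelineConfig | None = None,
    fit_model: bool = True,
    reduce_model: bool = False,
) -> PipelineResult:
    """Classify every trial, merge labels onto interval SDs, and (optionally)
    fit the log-SD variability model.

    Per-trial failures are collected and reported without aborting the batch.
    """
    cfg = config or PipelineConfig()
    if not trials:
        raise ValueError("need at least one trial")
    label_rows = []
    all_records: list[VariabilityRecord] = []
    failures: list[tuple[str, str]] = []
    for trial in trials:
        ident = (
            f"{trial.meta.subject_id}/{trial.meta.stimulus}/"
            f"{trial.meta.tempo_offset:+d}"
        )
        try:
            labels, records = process_trial(trial, cfg)
        except (TrialDataError, ValueError) as exc:
            log.warning("trial %s failed: %s", ident, exc)
            failures.append((ident, str(exc)))
            continue
        for lab in labels:
            label_rows.append(
                {
                    "subject_id": trial.meta.subject_id,
                    "stimulus": trial.meta.stimulus,
                    "tempo_offset": trial.meta.tempo_offset,
                    "window_index": lab.window_index,
                    "circ_p": lab.circ_p,
                    "slope_p": lab.slope_p,
                    "circ_label": lab.circ_label,
                    "slope_label": lab.slope_label,
                    "final_label": lab.final_label,
                }
            )
        all_records.extend(records)

    labels_df = pd.DataFrame(label_rows)
    fit = None
    if fit_model and all_records:
        try:
            if reduce_model:
                fit = model_reduction(all_records)
            else:
                fit = fit_variability_model(all_records)
        except TrialDataError as exc:
            log.warning("variability model not fitted: %s", exc)
            failures.append(("variability_model", str(exc)))
    return PipelineResult(
        labels=labels_df, records=all_records, fit=fit, failures=failures
    )
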