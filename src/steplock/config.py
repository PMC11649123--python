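"""Pipeline configuration: every tunable constant in one place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Constants of the windowed classification pipeline.

    window_length_s
        Length of each analysis window (s).  20 s gives nine windows over a
        standard 180-s trial and 20-30 steps per window at walking cadence.
    trial_duration_s
        Nominal trial length; observations at or beyond it are discarded.
    alpha_circ, alpha_slope
        Significance levels for the circular uniformity test and for the
        window-specific slope test.
    outlier_k
        Half-width of the interval cleaning band, median +/- k sd.
    min_obs_per_window
        Windows with fewer observations are labelled unevaluable; both the
        circular-range p-value and the slope BLUP are unstable at very
        small n.
    """

    window_length_s: float = 20.0
    trial_duration_s: float = 180.0
    alpha_circ: float = 0.05
    alpha_slope: float = 0.05
    outlier_k: float = 3.0
    min_obs_per_window: int = 8
    bonferroni_slope: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.window_length_s <= 0 or self.trial_duration_s <= 0:
            raise ValueError("window and trial lengths must be positive")
        for a in (self.alpha_circ, self.alpha_slope):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha must lie in (0, 1)")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")
        if self.min_obs_per_window < 2:
            raise ValueError("min_obs_per_window must be at least 2")

    @property
    def n_windows(self) -> int:
        ratio = self.trial_duration_s / self.window_length_s
        n = int(round(ratio))
        if abs(ratio - n) > 1e-9:
            raise ValueError("window_length_s must divide trial_duration_s")
        return n

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
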