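"""Domain types and file I/O for step/beat event recordings.

A trial is one three-minute walk to an auditory stimulus (music or a
metronome) whose beat stream has been detuned by a fixed percentage of the
participant's baseline comfortable cadence.  The raw observables are two
ordered event-time streams, footfalls ("steps") and stimulus beats, in
seconds from trial start.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Stimulus levels of the standard two-block design.
STIMULI: tuple[str, ...] = ("metronome", "music")

#: Tempo detuning levels, percent of baseline comfortable cadence.
TEMPO_OFFSETS: tuple[int, ...] = (-12, -8, -4, 0, 4, 8, 12)

EVENT_KINDS = ("step", "beat")


class TrialFormatError(ValueError):
    """A trial file does not have the expected columns/encoding."""


class TrialDataError(ValueError):
    """A trial file parses but violates a data invariant."""


def tempo_label(offset: int) -> str:
    """Render a signed tempo offset as a compact factor label.

    ``-12 -> "n12"``, ``0 -> "0"``, ``+8 -> "p8"``.  These labels are the
    coefficient-name dialect used in model output.
    """
    offset = int(offset)
    if offset == 0:
        return "0"
    return ("p" if offset > 0 else "n") + str(abs(offset))


@dataclass(frozen=True)
class TrialMeta:
    """Experimental metadata for one trial.

    Parameters
    ----------
    subject_id : opaque participant identifier.
    stimulus : stimulus block label; the standard design uses
        :data:`STIMULI` (``metronome``/``music``).
    tempo_offset : signed percent offset from baseline cadence; the standard
        design uses :data:`TEMPO_OFFSETS`.
    baseline_cadence : baseline comfortable cadence in steps per minute.
    """

    subject_id: str
    stimulus: str
    tempo_offset: int
    baseline_cadence: float = 75.0

    def __post_init__(self) -> None:
        if not str(self.subject_id):
            raise ValueError("subject_id must be a non-empty string")
        if not str(self.stimulus):
            raise ValueError("stimulus must be a non-empty label")
        if self.baseline_cadence <= 0:
            raise ValueError("baseline_cadence must be positive")
        object.__setattr__(self, "tempo_offset", int(self.tempo_offset))

    @property
    def tempo_bpm(self) -> float:
        """Beat rate of the stimulus implied by the tempo offset (beats/min)."""
        return self.baseline_cadence * (1.0 + self.tempo_offset / 100.0)

    @property
    def tempo_label(self) -> str:
        return tempo_label(self.tempo_offset)


@dataclass(frozen=True)
class EventSeries:
    """An ordered stream of event times (seconds from trial start)."""

    kind: str
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}, got {self.kind!r}")
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise TrialDataError(f"{self.kind} stream must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(t)):
            raise TrialDataError(f"{self.kind} stream contains non-finite times")
        if t[0] < 0:
            raise TrialDataError(f"{self.kind} stream contains negative times")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            i = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise TrialDataError(
                f"{self.kind} times must be strictly increasing; "
                f"violation at position {i} (t={t[i]:.6f})"
            )
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class Trial:
    """One trial: metadata plus its step and beat event streams."""

    meta: TrialMeta
    steps: EventSeries
    beats: EventSeries
    duration: float = 180.0

    def __post_init__(self) -> None:
        if self.steps.kind != "step":
            raise ValueError("steps must be an EventSeries of kind 'step'")
        if self.beats.kind != "beat":
            raise ValueError("beats must be an EventSeries of kind 'beat'")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _sorted_kind(df: pd.DataFrame, kind: str) -> np.ndarray:
    sub = df[df["event_kind"] == kind]
    if sub.empty:
        raise TrialDataError(f"trial file contains no {kind!r} events")
    times = sub["time_s"].to_numpy(dtype=float)
    order = np.argsort(times, kind="stable")
    times = times[order]
    dup = np.flatnonzero(np.diff(times) == 0)
    if dup.size:
        # report the original file row (1-based, counting the header)
        row = int(sub.index[order[dup[0] + 1]]) + 2
        raise TrialDataError(
            f"duplicate {kind} time {times[dup[0]]:.6f} at file row {row}"
        )
    return times


def read_trial(path: str | Path, meta: TrialMeta, duration: float = 180.0) -> Trial:
    """Read a trial from a delimited text table of (event_kind, time_s).

    Events are split by kind and sorted by time; an exactly repeated time
    within one kind is rejected as a data error naming the offending row.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise TrialFormatError(f"cannot parse trial file {path}: {exc}") from exc
    missing = {"event_kind", "time_s"} - set(df.columns)
    if missing:
        raise TrialFormatError(
            f"trial file {path} is missing column(s) {sorted(missing)}"
        )
    try:
        df["time_s"] = pd.to_numeric(df["time_s"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise TrialFormatError(f"non-numeric time_s in {path}: {exc}") from exc
    steps = EventSeries("step", _sorted_kind(df, "step"))
    beats = EventSeries("beat", _sorted_kind(df, "beat"))
    return Trial(meta=meta, steps=steps, beats=beats, duration=duration)


def write_trial(trial: Trial, path: str | Path) -> None:
    """Write a trial as a CSV table of (event_kind, time_s), 6-decimal times."""
    frames = []
    for series in (trial.steps, trial.beats):
        frames.append(
            pd.DataFrame({"event_kind": series.kind, "time_s": series.times})
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.6f")


def enumerate_design(
    stimuli: Sequence[str] = STIMULI,
    tempi: Sequence[int] = TEMPO_OFFSETS,
    subject_id: str = "S01",
    baseline_cadence: float = 75.0,
) -> list[TrialMeta]:
    """Enumerate the full stimulus x tempo cross for one subject.

    The order is deterministic: stimuli outer, tempi inner.  The default
    arguments give the standard 2 x 7 = 14-condition design.
    """
    stimuli = list(stimuli)
    tempi = list(tempi)
    if not stimuli or not tempi:
        raise ValueError("stimuli and tempi must both be non-empty")
    if len(set(stimuli)) != len(stimuli):
        raise ValueError("duplicate stimulus levels")
    if len(set(tempi)) != len(tempi):
        raise ValueError("duplicate tempo levels")
    return [
        TrialMeta(
            subject_id=subject_id,
            stimulus=s,
            tempo_offset=t,
            baseline_cadence=baseline_cadence,
        )
        for s in stimuli
        for t in tempi
    ]
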