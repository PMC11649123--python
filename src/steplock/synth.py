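"""Synthetic walking-to-beat trials with known per-window coupling labels.

Real recordings of this paradigm are not publicly available, so the package
ships a generator that emulates their event structure: an isochronous beat
stream at the trial's tempo, and a step stream whose relationship to the
beats switches between regimes along a segment plan:

``locked``
    one step per beat at a fixed mean phase offset, with von Mises phase
    jitter (concentration kappa) and Gaussian timing noise — concentrated,
    trend-flat rPA;
``unlocked_drift``
    isochronous steps whose period is detuned from the beat period by a
    fixed percentage — rPA advances ~360 * detuning/100 degrees per beat
    and wraps;
``unlocked_uniform``
    one step per beat at an independent uniform phase — rPA uniform on the
    circle.

Ground-truth window labels come from majority occupancy of each window by
locked segments.  A second generator draws per-window interval SDs directly
from the log-linear variability model for parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .classifier import LOCKED, UNLOCKED
from .io_model import EventSeries, Trial, TrialMeta, enumerate_design
from .variability import (
    VariabilityRecord,
    design_matrix,
    INTERACTION_BLOCKS,
    records_frame,
)

REGIMES = ("locked", "unlocked_drift", "unlocked_uniform")

#: effect magnitudes used as the default truth of the variability generator:
#: a realistic parameter set for per-window log inter-step-interval SD
#: (millisecond-like scale; the intercept only sets the overall unit).
DEFAULT_VARIABILITY_COEFFICIENTS: dict[str, float] = {
    "(Intercept)": 2.9725,
    "Tempi: n12": 0.1601,
    "Tempi: n4": 0.0125,
    "Tempi: n8": 0.1276,
    "Tempi: p12": -0.1970,
    "Tempi: p4": -0.0562,
    "Tempi: p8": -0.1241,
    "Stimuli: music": 0.2254,
    "Window_lab_resc": 0.0,
    "Lock_lab: unlocked": 0.0594,
    "Tempi: n12 * Stimuli: music": -0.1945,
    "Tempi: n4 * Stimuli: music": -0.0200,
    "Tempi: n8 * Stimuli: music": -0.1196,
    "Tempi: p12 * Stimuli: music": 0.0016,
    "Tempi: p4 * Stimuli: music": -0.1282,
    "Tempi: p8 * Stimuli: music": -0.0432,
    "Tempi: n12 * Lock_lab: unlocked": 0.0518,
    "Tempi: n4 * Lock_lab: unlocked": 0.0162,
    "Tempi: n8 * Lock_lab: unlocked": -0.0304,
    "Tempi: p12 * Lock_lab: unlocked": 0.2790,
    "Tempi: p4 * Lock_lab: unlocked": 0.0703,
    "Tempi: p8 * Lock_lab: unlocked": 0.2064,
}


@dataclass(frozen=True)
class Segment:
    """One regime segment of a trial's coupling plan."""

    start: float
    end: float
    regime: str
    offset_deg: float = -30.0  # locked: mean phase offset (negative = before beat)
    kappa: float = 8.0  # locked: von Mises concentration of phase jitter
    detuning_pct: float = 0.0  # drift: step-period detuning, percent of IBI

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.regime == "locked" and self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.regime == "unlocked_drift" and self.detuning_pct == 0:
            raise ValueError("drift segment needs a nonzero detuning")


@dataclass(frozen=True)
class SegmentPlan:
    """Ordered segments tiling [0, duration) without gaps or overlap."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ValueError("plan must contain at least one segment")
        if abs(segs[0].start) > 1e-9:
            raise ValueError("plan must start at 0")
        for a, b in zip(segs, segs[1:]):
            if abs(a.end - b.start) > 1e-9:
                raise ValueError("segments must tile the trial without gaps")
        object.__setattr__(self, "segments", segs)

    @property
    def duration(self) -> float:
        return self.segments[-1].end

    def locked_occupancy(self, start: float, end: float) -> float:
        """Fraction of [start, end) covered by locked segments."""
        total = 0.0
        for seg in self.segments:
            if seg.regime != "locked":
                continue
            total += max(0.0, min(end, seg.end) - max(start, seg.start))
        return total / (end - start)


@dataclass(frozen=True)
class GroundTruth:
    """True per-window labels derived from a plan by majority occupancy."""

    labels: tuple[str, ...]

    @classmethod
    def from_plan(
        cls, plan: SegmentPlan, window_length: float, n_windows: int
    ) -> "GroundTruth":
        labels = []
        for k in range(1, n_windows + 1):
            frac = plan.locked_occupancy((k - 1) * window_length, k * window_length)
            labels.append(LOCKED if frac > 0.5 else UNLOCKED)
        return cls(tuple(labels))

    def __len__(self) -> int:
        return len(self.labels)


def generate_beats(tempo_bpm: float, duration: float) -> EventSeries:
    """Isochronous beat stream: beats at k * 60/tempo_bpm while < duration."""
    if tempo_bpm <= 0:
        raise ValueError("tempo_bpm must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    period = 60.0 / tempo_bpm
    times = period * np.arange(int(np.ceil(duration / period)) + 1)
    return EventSeries("beat", times[times < duration - 1e-9])


def generate_steps(
    beats: EventSeries,
    plan: SegmentPlan,
    timing_noise_sd: float = 0.01,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_separation: float = 1e-3,
) -> EventSeries:
    """Generate a step stream following the plan's coupling regimes.

    All randomness flows from a single generator (``rng`` if given, else one
    seeded with ``seed``).  Jitter collisions are resolved by pushing steps
    apart by ``min_separation``; output times are strictly increasing and
    clipped to [0, duration).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    bt = beats.times
    if bt.size < 2:
        raise ValueError("need at least two beats")
    ibi = np.diff(bt)
    duration = plan.duration
    chunks: list[np.ndarray] = []
    for seg in plan.segments:
        # beats that start an interval inside this segment
        sel = np.flatnonzero((bt >= seg.start - 1e-12) & (bt < seg.end - 1e-12))
        sel = sel[sel < bt.size - 1]
        if seg.regime == "locked":
            theta = rng.vonmises(np.deg2rad(seg.offset_deg), seg.kappa, size=sel.size)
            st = bt[sel] + np.rad2deg(theta) / 360.0 * ibi[sel]
            if timing_noise_sd > 0:
                st = st + rng.normal(0.0, timing_noise_sd, size=sel.size)
        elif seg.regime == "unlocked_uniform":
            st = bt[sel] + rng.uniform(0.0, 1.0, size=sel.size) * ibi[sel]
        else:  # unlocked_drift
            base_ibi = float(np.median(ibi[sel])) if sel.size else float(np.median(ibi))
            period = base_ibi * (1.0 + seg.detuning_pct / 100.0)
            n = int(np.ceil((seg.end - seg.start) / period)) + 1
            st = seg.start + rng.uniform(0.0, period) + period * np.arange(n)
            st = st[st < seg.end]
            if timing_noise_sd > 0:
                st = st + rng.normal(0.0, timing_noise_sd, size=st.size)
        chunks.append(st)
    times = np.sort(np.concatenate(chunks))
    times = times[(times >= 0.0) & (times < duration)]
    # resolve collisions by minimal separation
    for _ in range(10):
        gaps = np.diff(times)
        bad = np.flatnonzero(gaps < min_separation)
        if bad.size == 0:
            break
        times[bad + 1] = times[bad] + min_separation
    times = times[times < duration]
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("could not produce strictly increasing step times")
    return EventSeries("step", times)


def aligned_plan_sampler(
    window_length: float = 20.0,
    windows_per_segment: int = 3,
    p_locked: float = 0.5,
    p_uniform: float = 0.25,
    offset_deg: float = -30.0,
    kappa: float = 8.0,
    detuning_range: tuple[float, float] = (4.0, 8.0),
) -> Callable[[np.random.Generator, float], SegmentPlan]:
    """Sampler of plans whose segment boundaries sit on window boundaries.

    Each segment spans ``windows_per_segment`` windows and draws its regime
    independently: locked with probability ``p_locked``, uniform with
    ``p_uniform``, otherwise drift with a detuning of random sign drawn
    uniformly from ``detuning_range`` (percent of the inter-beat interval).
    Aligned boundaries make the majority-occupancy ground truth unambiguous.
    """

    def sample(rng: np.random.Generator, duration: float) -> SegmentPlan:
        seg_len = window_length * windows_per_segment
        n_seg = int(round(duration / seg_len))
        if abs(duration - n_seg * seg_len) > 1e-9 or n_seg < 1:
            raise ValueError("segment length must tile the trial duration")
        segments = []
        for i in range(n_seg):
            start, end = i * seg_len, (i + 1) * seg_len
            u = rng.uniform()
            if u < p_locked:
                segments.append(
                    Segment(start, end, "locked", offset_deg=offset_deg, kappa=kappa)
                )
            elif u < p_locked + p_uniform:
                segments.append(Segment(start, end, "unlocked_uniform"))
            else:
                det = rng.uniform(*detuning_range) * rng.choice([-1.0, 1.0])
                segments.append(
                    Segment(start, end, "unlocked_drift", detuning_pct=det)
                )
        return SegmentPlan(tuple(segments))

    return sample


def generate_trial_set(
    design: Sequence[TrialMeta],
    seed: int | None = None,
    plan_sampler: Callable[[np.random.Generator, float], SegmentPlan] | None = None,
    duration: float = 180.0,
    window_length: float = 20.0,
    timing_noise_sd: float = 0.01,
) -> list[tuple[Trial, GroundTruth]]:
    """Generate one trial per design condition with ground-truth labels."""
    rng = np.random.default_rng(seed)
    sampler = plan_sampler or aligned_plan_sampler(window_length=window_length)
    n_windows = int(round(duration / window_length))
    out = []
    for meta in design:
        plan = sampler(rng, duration)
        beats = generate_beats(meta.tempo_bpm, duration)
        steps = generate_steps(
            beats, plan, timing_noise_sd=timing_noise_sd, rng=rng
        )
        trial = Trial(meta=meta, steps=steps, beats=beats, duration=duration)
        out.append((trial, GroundTruth.from_plan(plan, window_length, n_windows)))
    return out


def generate_variability_dataset(
    coefficients: dict[str, float] | None = None,
    n_subjects: int = 12,
    design: Sequence[TrialMeta] | None = None,
    seed: int | None = None,
    subject_sd: float = 0.15,
    resid_sd: float = 0.2,
    n_windows: int = 9,
    lock_prob: float = 0.5,
) -> list[VariabilityRecord]:
    """Draw per-window SD records directly from the log-linear model.

    For every subject x condition x window cell a lock label is drawn
    Bernoulli(``lock_prob``); log S is the linear predictor under
    ``coefficients`` (defaults to
    :data:`DEFAULT_VARIABILITY_COEFFICIENTS`) plus a subject intercept
    (sd ``subject_sd``) and residual noise (sd ``resid_sd``), and S is its
    exponential.  The default design size is 12 subjects x 14 conditions x
    9 windows.
    """
    rng = np.random.default_rng(seed)
    coefficients = (
        dict(DEFAULT_VARIABILITY_COEFFICIENTS) if coefficients is None else dict(coefficients)
    )
    design = list(design) if design is not None else enumerate_design()
    subjects = [f"S{i + 1:02d}" for i in range(n_subjects)]
    b_subj = dict(zip(subjects, rng.normal(0.0, subject_sd, size=n_subjects)))

    rows = []
    for subj in subjects:
        for meta in design:
            for k in range(1, n_windows + 1):
                rows.append(
                    VariabilityRecord(
                        subject_id=subj,
                        stimulus=meta.stimulus,
                        tempo_offset=meta.tempo_offset,
                        window_index=k,
                        lock_label=LOCKED if rng.uniform() >= lock_prob else UNLOCKED,
                        sd_isi=1.0,  # placeholder until drawn below
                        n_steps=25,
                    )
                )
    frame = records_frame(rows)
    X = design_matrix(frame, interactions=INTERACTION_BLOCKS, drop_empty=False)
    unknown = set(coefficients) - set(X.columns)
    if unknown:
        raise ValueError(f"unknown coefficient name(s): {sorted(unknown)}")
    beta = np.array([coefficients.get(c, 0.0) for c in X.columns])
    log_s = X.to_numpy() @ beta
    log_s += np.array([b_subj[s] for s in frame["subject_id"]])
    if resid_sd > 0:
        log_s += rng.normal(0.0, resid_sd, size=len(frame))
    sds = np.exp(log_s)
    return [
        VariabilityRecord(
            subject_id=r.subject_id,
            stimulus=r.stimulus,
            tempo_offset=r.tempo_offset,
            window_index=r.window_index,
            lock_label=r.lock_label,
            sd_isi=float(s),
            n_steps=r.n_steps,
        )
        for r, s in zip(rows, sds)
    ]
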