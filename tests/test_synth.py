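import numpy as np
import pytest

from steplock import (
    LOCKED,
    UNLOCKED,
    circular_mean_and_R,
    circular_uniformity_test,
    enumerate_design,
    relative_phase_angles,
)
from steplock.synth import (
    GroundTruth,
    Segment,
    SegmentPlan,
    aligned_plan_sampler,
    generate_beats,
    generate_steps,
    generate_trial_set,
    generate_variability_dataset,
)


class TestGenerateBeats:
    def test_unit_spacing(self):
        beats = generate_beats(60.0, 10.0)
        np.testing.assert_allclose(beats.times, np.arange(10.0))

    def test_walking_tempo_count(self):
        assert len(generate_beats(75.0, 180.0)) == 225

    def test_offset_tempo_stream(self):
        # +12% on baseline 75 -> 84 bpm
        beats = generate_beats(84.0, 180.0)
        assert np.diff(beats.times)[0] == pytest.approx(60.0 / 84.0)


class TestGenerateSteps:
    def test_noiseless_lock_coincides_with_beats(self):
        beats = generate_beats(75.0, 60.0)
        plan = SegmentPlan(
            (Segment(0, 60, "locked", offset_deg=0.0, kappa=1e9),)
        )
        steps = generate_steps(beats, plan, timing_noise_sd=0.0, seed=0)
        ps, _ = relative_phase_angles(steps, beats)
        assert np.max(np.abs(ps.angles)) < 0.5

    def test_drift_rate_matches_detuning(self):
        # 5% detuning at IBI 0.8 s: rPA advances ~18 degrees per beat
        beats = generate_beats(75.0, 180.0)
        plan = SegmentPlan((Segment(0, 180, "unlocked_drift", detuning_pct=5.0),))
        steps = generate_steps(beats, plan, timing_noise_sd=0.0, seed=1)
        ps, _ = relative_phase_angles(steps, beats)
        inc = np.diff(ps.angles)
        wrapped = np.mod(inc + 180.0, 360.0) - 180.0
        assert np.mean(wrapped) == pytest.approx(18.0, abs=1.0)

    def test_uniform_regime_is_null_for_circular_test(self):
        beats = generate_beats(75.0, 180.0)
        plan = SegmentPlan((Segment(0, 180, "unlocked_uniform"),))
        rejections = 0
        n_windows = 0
        for seed in range(5):
            steps = generate_steps(beats, plan, seed=seed)
            ps, _ = relative_phase_angles(steps, beats)
            for k in range(9):
                sel = (ps.times >= k * 20.0) & (ps.times < (k + 1) * 20.0)
                if sel.sum() >= 8:
                    n_windows += 1
                    rejections += circular_uniformity_test(ps.angles[sel]).reject
        assert n_windows >= 40
        assert rejections / n_windows < 0.10

    def test_locked_windows_are_concentrated(self):
        beats = generate_beats(75.0, 180.0)
        plan = SegmentPlan((Segment(0, 180, "locked", offset_deg=-30, kappa=8),))
        steps = generate_steps(beats, plan, seed=2)
        ps, _ = relative_phase_angles(steps, beats)
        for k in range(9):
            sel = (ps.times >= k * 20.0) & (ps.times < (k + 1) * 20.0)
            _, r = circular_mean_and_R(ps.angles[sel])
            assert r > 0.7

    def test_strictly_increasing_within_duration(self):
        beats = generate_beats(80.0, 180.0)
        sampler = aligned_plan_sampler()
        rng = np.random.default_rng(3)
        for _ in range(5):
            plan = sampler(rng, 180.0)
            steps = generate_steps(beats, plan, rng=rng)
            assert np.all(np.diff(steps.times) > 0)
            assert steps.times[0] >= 0.0 and steps.times[-1] < 180.0

    def test_default_cadence_gives_paper_band_of_steps_per_window(self):
        beats = generate_beats(75.0, 180.0)
        plan = SegmentPlan((Segment(0, 180, "locked"),))
        steps = generate_steps(beats, plan, seed=4)
        counts = [
            ((steps.times >= k * 20.0) & (steps.times < (k + 1) * 20.0)).sum()
            for k in range(9)
        ]
        assert all(20 <= c <= 30 for c in counts)


class TestTrialSet:
    def test_full_design_with_truth(self):
        out = generate_trial_set(enumerate_design(), seed=0)
        assert len(out) == 14
        for trial, truth in out:
            assert len(truth) == 9
            assert set(truth.labels) <= {LOCKED, UNLOCKED}

    def test_reproducible_given_seed(self):
        a = generate_trial_set(enumerate_design(), seed=9)
        b = generate_trial_set(enumerate_design(), seed=9)
        for (ta, _), (tb, _) in zip(a, b):
            np.testing.assert_array_equal(ta.steps.times, tb.steps.times)
            np.testing.assert_array_equal(ta.beats.times, tb.beats.times)

    def test_aligned_boundaries_make_truth_unambiguous(self):
        plan = SegmentPlan(
            (
                Segment(0, 60, "locked"),
                Segment(60, 120, "unlocked_uniform"),
                Segment(120, 180, "locked"),
            )
        )
        truth = GroundTruth.from_plan(plan, 20.0, 9)
        assert truth.labels == (
            LOCKED, LOCKED, LOCKED,
            UNLOCKED, UNLOCKED, UNLOCKED,
            LOCKED, LOCKED, LOCKED,
        )
        for k in range(1, 10):
            frac = plan.locked_occupancy((k - 1) * 20.0, k * 20.0)
            assert frac in (0.0, 1.0)


class TestVariabilityGenerator:
    def test_degenerate_generator_is_deterministic_exponential(self):
        records = generate_variability_dataset(
            coefficients={"(Intercept)": 1.5},
            subject_sd=0.0,
            resid_sd=0.0,
            seed=0,
            n_subjects=2,
        )
        assert all(r.sd_isi == pytest.approx(np.exp(1.5)) for r in records)

    def test_stimulus_contrast_matches_coefficient_at_large_n(self):
        # music minus metronome at reference tempo/lock ~ the set effect
        records = generate_variability_dataset(seed=1, n_subjects=60)
        logs = {}
        for stim in ("music", "metronome"):
            vals = [
                np.log(r.sd_isi)
                for r in records
                if r.stimulus == stim and r.tempo_offset == 0
                and r.lock_label == LOCKED
            ]
            logs[stim] = np.mean(vals)
        diff = logs["music"] - logs["metronome"]
        assert diff == pytest.approx(0.2254, abs=0.03)

    def test_same_seed_same_table(self):
        a = generate_variability_dataset(seed=2, n_subjects=3)
        b = generate_variability_dataset(seed=2, n_subjects=3)
        assert a == b

    def test_unknown_coefficient_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            generate_variability_dataset(
                coefficients={"Tempi: q7": 1.0}, seed=0, n_subjects=2
            )
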