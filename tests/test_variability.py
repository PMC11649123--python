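import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from steplock import (
    LOCKED,
    UNEVALUABLE,
    UNLOCKED,
    TrialDataError,
    TrialMeta,
    WindowLabel,
    fit_variability_model,
    merge_labels,
    model_reduction,
    window_sd,
)
from steplock.preprocess import Window, WindowedSeries
from steplock.synth import (
    DEFAULT_VARIABILITY_COEFFICIENTS,
    generate_variability_dataset,
)
from steplock.variability import VariabilityRecord

META = TrialMeta("S01", "music", -8)


class TestWindowSd:
    def test_constant_values(self):
        assert window_sd([0.5, 0.5, 0.5]) == 0.0

    def test_two_point_hand_value(self):
        assert window_sd([0.4, 0.6]) == pytest.approx(0.1)

    def test_single_value_unevaluable(self):
        with pytest.raises(TrialDataError):
            window_sd([0.5])

    @given(st.lists(st.floats(0.01, 5.0), min_size=2, max_size=50))
    def test_matches_two_pass_brute_force(self, values):
        v = np.asarray(values)
        mu = sum(values) / len(values)
        brute = math.sqrt(sum((x - mu) ** 2 for x in values) / len(values))
        assert window_sd(v) == pytest.approx(brute, abs=1e-12)

    @given(
        st.lists(st.floats(0.01, 5.0), min_size=2, max_size=20),
        st.floats(-2.0, 2.0),
        st.floats(0.1, 3.0),
    )
    def test_shift_and_scale_identities(self, values, shift, scale):
        v = np.asarray(values)
        assert window_sd(v + shift) == pytest.approx(window_sd(v), abs=1e-9)
        assert window_sd(v * scale) == pytest.approx(
            scale * window_sd(v), rel=1e-9
        )


def isi_windows(n=9, obs_per=20, sd=0.02, rng=None):
    rng = rng or np.random.default_rng(0)
    windows = []
    for k in range(1, n + 1):
        t = np.sort(rng.uniform((k - 1) * 20.0, k * 20.0, obs_per))
        windows.append(Window(k, t, rng.normal(0.8, sd, obs_per)))
    return WindowedSeries(20.0, tuple(windows))


def labels_for(n=9, unevaluable=()):
    out = []
    for k in range(1, n + 1):
        lab = UNEVALUABLE if k in unevaluable else (LOCKED if k % 2 else UNLOCKED)
        out.append(WindowLabel(k, lab, lab, lab, 0.01, 0.5))
    return out


class TestMergeLabels:
    def test_aligned_merge(self):
        records, dropped = merge_labels(isi_windows(), labels_for(), META)
        assert len(records) == 9 and not dropped
        assert {r.lock_label for r in records} == {LOCKED, UNLOCKED}
        assert all(r.sd_isi > 0 for r in records)

    def test_unevaluable_window_dropped(self):
        records, dropped = merge_labels(
            isi_windows(), labels_for(unevaluable=(5,)), META
        )
        assert len(records) == 8 and dropped == [5]

    def test_window_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            merge_labels(
                isi_windows(), labels_for(), META, label_window_length=30.0
            )

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="count"):
            merge_labels(isi_windows(), labels_for(n=8), META)

    def test_window_rescaling(self):
        records, _ = merge_labels(isi_windows(), labels_for(), META)
        assert [r.window_rescaled for r in records] == [
            k / 10 for k in range(1, 10)
        ]


class TestFitVariabilityModel:
    def test_parameter_recovery_within_3_se(self):
        records = generate_variability_dataset(seed=0)
        fit = fit_variability_model(records)
        for name, est in fit.params.items():
            truth = DEFAULT_VARIABILITY_COEFFICIENTS.get(name, 0.0)
            assert abs(est - truth) < 3 * fit.se[name], name

    def test_null_model_recovery(self):
        records = generate_variability_dataset(
            coefficients={"(Intercept)": 1.7}, seed=1
        )
        fit = fit_variability_model(records)
        assert fit.params["(Intercept)"] == pytest.approx(
            1.7, abs=3 * fit.se["(Intercept)"]
        )
        for name, est in fit.params.items():
            if name != "(Intercept)":
                assert abs(est) < 3.5 * fit.se[name], name

    def test_duplicated_records_leave_estimates_stable(self):
        records = generate_variability_dataset(seed=2, n_subjects=6)
        fit = fit_variability_model(records)
        fit2 = fit_variability_model(records + records)
        for name in fit.params:
            assert fit2.params[name] == pytest.approx(fit.params[name], abs=1e-3)
            assert fit2.se[name] < fit.se[name]

    def test_log_scale_equivariance(self):
        records = generate_variability_dataset(seed=3, n_subjects=6)
        scaled = [
            VariabilityRecord(
                r.subject_id, r.stimulus, r.tempo_offset, r.window_index,
                r.lock_label, r.sd_isi * 1000.0, r.n_steps,
            )
            for r in records
        ]
        a = fit_variability_model(records)
        b = fit_variability_model(scaled)
        assert b.params["(Intercept)"] - a.params["(Intercept)"] == pytest.approx(
            math.log(1000.0), abs=1e-6
        )
        for name in a.params:
            if name != "(Intercept)":
                assert b.params[name] == pytest.approx(a.params[name], abs=1e-6)

    def test_zero_sd_rejected_with_guidance(self):
        records = generate_variability_dataset(seed=4, n_subjects=3)
        broken = records + [
            VariabilityRecord("S01", "music", 0, 1, LOCKED, 0.0, 20)
        ]
        with pytest.raises(TrialDataError, match="floor"):
            fit_variability_model(broken)

    def test_coefficient_table_layout(self):
        fit = fit_variability_model(generate_variability_dataset(seed=5, n_subjects=4))
        assert list(fit.table.columns) == [
            "Parameter", "Estimate", "Std. error", "t", "p-value"
        ]
        names = list(fit.table["Parameter"])
        assert names[0] == "(Intercept)"
        assert "Tempi: n12" in names and "Lock_lab: unlocked" in names
        assert "Tempi: p12 * Lock_lab: unlocked" in names
        assert (fit.table["Std. error"] > 0).all()


class TestModelReduction:
    def test_true_interaction_blocks_retained(self):
        # truth holds tempo x stimulus and tempo x lock effects, nothing else
        records = generate_variability_dataset(seed=6, n_subjects=16)
        fit = model_reduction(records)
        assert set(fit.interactions) == {("tempi", "stimuli"), ("tempi", "lock")}

    def test_no_interactions_reduces_to_main_effects(self):
        coeffs = {
            k: v
            for k, v in DEFAULT_VARIABILITY_COEFFICIENTS.items()
            if " * " not in k
        }
        records = generate_variability_dataset(coefficients=coeffs, seed=7)
        fit = model_reduction(records)
        assert fit.interactions == ()
        assert all(" * " not in p for p in fit.table["Parameter"])

    def test_main_effects_never_dropped(self):
        # the window trend is truly null yet must survive reduction
        records = generate_variability_dataset(seed=8)
        fit = model_reduction(records)
        names = set(fit.table["Parameter"])
        assert {"Window_lab_resc", "Lock_lab: unlocked", "Stimuli: music"} <= names
        assert {f"Tempi: {l}" for l in ("n12", "n8", "n4", "p4", "p8", "p12")} <= names
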