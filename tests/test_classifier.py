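"""Threshold learning, classification, LOO validation, separation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from kinespeed.classifier import (ThresholdPair, classify, classify_many,
                                  fit_thresholds, fit_thresholds_intraclass,
                                  group_separation_tests, loo_from_table,
                                  partial_motion_analysis)

CLASS_INDEX = {"slow": 0, "normal": 1, "fast": 2}


def labeled(slow, normal, fast):
    values = np.concatenate([slow, normal, fast])
    labels = np.array(["slow"] * len(slow) + ["normal"] * len(normal)
                      + ["fast"] * len(fast))
    return values, labels


def three_gaussians(rng, n=100, means=(0.35, 1.0, 2.0), sd=0.1):
    return labeled(rng.normal(means[0], sd, n),
                   rng.normal(means[1], sd, n),
                   rng.normal(means[2], sd, n))


class TestFitThresholds:
    def test_midpoint_worked_example(self):
        values, labels = labeled([0.2, 0.3], [1.0, 1.1], [2.0, 2.2])
        thr = fit_thresholds(values, labels, method="midpoint")
        assert thr.thr1 == pytest.approx(0.65, rel=1e-12)
        assert thr.thr2 == pytest.approx(1.55, rel=1e-12)

    @pytest.mark.parametrize("method", ["valley", "midpoint"])
    def test_thresholds_sit_between_class_means(self, method):
        rng = np.random.default_rng(0)
        values, labels = three_gaussians(rng)
        thr = fit_thresholds(values, labels, method=method)
        means = {c: values[labels == c].mean() for c in CLASS_INDEX}
        assert means["slow"] < thr.thr1 < means["normal"]
        assert means["normal"] < thr.thr2 < means["fast"]

    def test_valley_agrees_with_midpoint_on_separated_classes(self):
        rng = np.random.default_rng(1)
        values, labels = three_gaussians(rng)
        valley = fit_thresholds(values, labels, method="valley")
        midpoint = fit_thresholds(values, labels, method="midpoint")
        gaps = [values[labels == "normal"].min() - values[labels == "slow"].max(),
                values[labels == "fast"].min() - values[labels == "normal"].max()]
        tol = min(abs(g) for g in gaps) / 2 + 0.05
        assert abs(valley.thr1 - midpoint.thr1) <= tol
        assert abs(valley.thr2 - midpoint.thr2) <= tol

    def test_valley_matches_fine_grid_density_scan(self):
        """Independent oracle: exhaustive argmin of the same KDE on a
        1e-4-of-range step grid between adjacent class means."""
        rng = np.random.default_rng(7)
        values, labels = three_gaussians(rng, sd=0.15)
        thr = fit_thresholds(values, labels, method="valley")
        kde = stats.gaussian_kde(values, bw_method="silverman")
        span = values.max() - values.min()
        means = {c: values[labels == c].mean() for c in CLASS_INDEX}
        for (lo, hi), got in [((means["slow"], means["normal"]), thr.thr1),
                              ((means["normal"], means["fast"]), thr.thr2)]:
            grid = np.arange(lo, hi, 1e-4 * span)[1:]
            expected = grid[np.argmin(kde(grid))]
            assert abs(got - expected) <= span / 256

    def test_empty_class_rejected(self):
        values, labels = labeled([0.2, 0.3], [1.0, 1.1], [])
        with pytest.raises(ValueError, match="no values"):
            fit_thresholds(values, labels)

    def test_unordered_class_means_rejected(self):
        values, labels = labeled([2.0, 2.1], [1.0, 1.1], [0.2, 0.3])
        with pytest.raises(ValueError, match="not ordered"):
            fit_thresholds(values, labels)

    def test_threshold_pair_invariant(self):
        with pytest.raises(ValueError, match="thr1"):
            ThresholdPair(1.5, 0.58)


class TestIntraclassThresholds:
    def test_identical_subjects(self):
        values, labels = labeled([0.4, 0.6], [1.4, 1.6], [2.4, 2.6])
        values = np.tile(values, 2)
        labels = np.tile(labels, 2)
        subjects = np.repeat(["A", "B"], 6)
        thr = fit_thresholds_intraclass(values, labels, subjects)
        assert thr.thr1 == pytest.approx(1.0, rel=1e-12)
        assert thr.thr2 == pytest.approx(2.0, rel=1e-12)

    def test_average_of_two_subjects(self):
        # subject A thresholds (0.4, 1.4); subject B thresholds (0.6, 1.6)
        a_vals, a_labs = labeled([0.3, 0.3], [0.5, 0.7], [2.1, 2.3])
        b_vals, b_labs = labeled([0.5, 0.5], [0.7, 0.9], [2.3, 2.5])
        values = np.concatenate([a_vals, b_vals])
        labels = np.concatenate([a_labs, b_labs])
        subjects = np.repeat(["A", "B"], 6)
        thr = fit_thresholds_intraclass(values, labels, subjects)
        assert thr.thr1 == pytest.approx(0.5, rel=1e-12)
        assert thr.thr2 == pytest.approx(1.5, rel=1e-12)

    def test_subject_missing_a_class(self):
        values, labels = labeled([0.2], [1.0], [2.0])
        with pytest.raises(ValueError, match="no values"):
            fit_thresholds_intraclass(values, labels, np.array(["A", "A", "B"]))


class TestClassify:
    THR = ThresholdPair(0.58, 1.50)

    @pytest.mark.parametrize("value,expected", [
        (0.50, "slow"),
        (1.00, "normal"),
        (2.00, "fast"),
        (0.58, "slow"),    # tie goes to the slower class
        (1.50, "normal"),
    ])
    def test_decision_rule(self, value, expected):
        assert classify(value, self.THR) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify(float("nan"), self.THR)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-5, 5), st.floats(0.001, 5))
    def test_monotone_in_value(self, v, dv):
        lo = CLASS_INDEX[classify(v, self.THR)]
        hi = CLASS_INDEX[classify(v + dv, self.THR)]
        assert hi >= lo

    def test_vectorized_matches_scalar(self):
        values = np.linspace(0, 3, 31)
        many = classify_many(values, self.THR)
        assert all(many[i] == classify(v, self.THR)
                   for i, v in enumerate(values))


def synthetic_table(rng, n_subjects=3, reps=5, means=(0.3, 1.0, 2.0),
                    sd=0.02):
    rows = []
    for s in range(n_subjects):
        for label, mean in zip(("slow", "normal", "fast"), means):
            for _ in range(reps):
                rows.append({"subject_id": f"S{s}",
                             "label": label,
                             "f1": rng.normal(mean, sd)})
    return pd.DataFrame(rows)


class TestLeaveOneSubjectOut:
    @pytest.mark.parametrize("protocol", ["inter", "intra"])
    def test_separable_classes_give_zero_error(self, protocol):
        table = synthetic_table(np.random.default_rng(0))
        report = loo_from_table(table, "f1", protocol)
        assert report.overall_error_pct == 0.0
        assert len(report.steps) == 3
        for step in report.steps:
            assert step["thr1"] < step["thr2"]

    def test_single_misclassification_arithmetic(self):
        """One outlier among 45 motions: 1/45 = 2.22% overall error."""
        table = synthetic_table(np.random.default_rng(3), sd=0.02)
        # subject S0's first slow motion drifts above the learned thr1
        idx = table[(table.subject_id == "S0") & (table.label == "slow")].index[0]
        table.loc[idx, "f1"] = 0.80
        report = loo_from_table(table, "f1", "inter", method="midpoint")
        assert report.overall_error_pct == pytest.approx(100 / 45, rel=1e-9)
        errors = sorted(s["error_pct"] for s in report.steps)
        assert errors == pytest.approx([0.0, 0.0, 100 / 15])

    def test_fold_errors_are_multiples_of_motion_granularity(self):
        rng = np.random.default_rng(12)
        table = synthetic_table(rng, n_subjects=4, sd=0.4)
        report = loo_from_table(table, "f1", "inter")
        for step in report.steps:
            multiple = step["error_pct"] / (100 / 15)
            assert multiple == pytest.approx(round(multiple), abs=1e-9)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(4)
        table = synthetic_table(rng, n_subjects=5, sd=0.3)
        shuffled = table.sample(frac=1, random_state=1).reset_index(drop=True)
        a = loo_from_table(table, "f1", "inter")
        b = loo_from_table(shuffled, "f1", "inter")
        assert a.overall_error_pct == b.overall_error_pct

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        table = synthetic_table(rng, n_subjects=4, sd=0.3)
        scaled = table.copy()
        scaled["f1"] = scaled["f1"] * 7.3
        a = loo_from_table(table, "f1", "inter")
        b = loo_from_table(scaled, "f1", "inter")
        assert a.overall_error_pct == b.overall_error_pct

    def test_needs_three_subjects(self):
        table = synthetic_table(np.random.default_rng(0), n_subjects=2)
        with pytest.raises(ValueError, match="3 subjects"):
            loo_from_table(table, "f1", "inter")

    def test_degenerate_training_raises_by_default(self):
        rng = np.random.default_rng(6)
        table = synthetic_table(rng, means=(1.0, 1.0, 1.0), sd=1e-6)
        with pytest.raises(ValueError):
            loo_from_table(table, "f1", "inter")

    def test_degenerate_training_chance_policy(self):
        rng = np.random.default_rng(6)
        table = synthetic_table(rng, means=(1.0, 1.0, 1.0), sd=1e-6)
        report = loo_from_table(table, "f1", "inter", on_degenerate="chance")
        assert report.overall_error_pct == pytest.approx(200 / 3, rel=1e-6)

    def test_report_frame_has_overall_row(self):
        table = synthetic_table(np.random.default_rng(0))
        frame = loo_from_table(table, "f1", "inter").to_frame()
        assert list(frame["step"])[-1] == "overall"
        assert len(frame) == 4


class TestPartialMotionAnalysis:
    def test_prefix_one_matches_full_loo(self, tiny_cohort):
        dataset, _ = tiny_cohort
        from kinespeed.classifier import loo_cross_validate
        full = loo_cross_validate(dataset, "HAND", "f1", protocol="inter")
        table = partial_motion_analysis(dataset, "HAND", "f1",
                                        protocol="inter", mode="prefix")
        last = table.iloc[-1]
        assert last["slice_end"] == 1.0
        assert last["overall_error_pct"] == full.overall_error_pct

    def test_window_rows_cover_the_ten_slices(self, tiny_cohort):
        dataset, _ = tiny_cohort
        table = partial_motion_analysis(dataset, "HAND", "f1",
                                        protocol="inter", mode="window")
        assert len(table) == 10
        assert table["available"].all()


class TestGroupSeparation:
    def test_strong_separation_is_significant(self):
        rng = np.random.default_rng(8)
        values, labels = three_gaussians(rng, n=10, sd=0.1)
        res = group_separation_tests(values, labels)
        assert res.anova_p < 0.01
        assert res.kruskal_p < 0.01
        assert res.n_per_class == {"slow": 10, "normal": 10, "fast": 10}

    def test_degenerate_constant_input_warns(self):
        values, labels = labeled([1.0] * 5, [1.0] * 5, [1.0] * 5)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = group_separation_tests(values, labels)
        assert np.isnan(res.anova_p) and np.isnan(res.kruskal_p)

    def test_small_class_rejected(self):
        values, labels = labeled([0.2], [1.0, 1.1], [2.0, 2.1])
        with pytest.raises(ValueError, match=">= 2"):
            group_separation_tests(values, labels)
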