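"""Metric definitions: confusion statistics, regression scores, fold error."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalxcrete.evaluation import (
    EvaluationReport,
    confusion_stats,
    fold_error_fraction,
    fold_errors,
    paired_split_comparison,
    range_split_report,
    regression_stats,
)
from renalxcrete.pk_core import PhysiologyConstants


def _labels_from_table(tp, fn, fp, tn):
    truth = ["pos"] * (tp + fn) + ["neg"] * (fp + tn)
    pred = ["pos"] * tp + ["neg"] * fn + ["pos"] * fp + ["neg"] * tn
    return pred, truth


class TestConfusionStats:
    def test_perfect_agreement(self):
        pred, truth = _labels_from_table(5, 0, 0, 5)
        stats = confusion_stats(pred, truth)
        assert stats["kappa"] == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in stats["balanced_accuracy"].values())

    def test_hand_computed_table(self):
        """TP=40 FN=10 FP=20 TN=30: po=0.7, pe=0.5, kappa=0.40."""
        pred, truth = _labels_from_table(40, 10, 20, 30)
        assert confusion_stats(pred, truth)["kappa"] == pytest.approx(0.40)

    def test_single_predicted_class_gives_zero_kappa(self):
        truth = ["a"] * 6 + ["b"] * 4
        assert confusion_stats(["a"] * 10, truth)["kappa"] == pytest.approx(0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_stats(["a"], ["a", "b"])

    def test_exhaustive_small_tables_match_hand_formula(self):
        """Cohen's Kappa agrees with direct (po-pe)/(1-pe) arithmetic on
        every 2x2 table with all cell counts <= 5."""
        for tp, fn, fp, tn in itertools.product(range(6), repeat=4):
            n = tp + fn + fp + tn
            if (tp + fn) == 0 or (fp + tn) == 0:
                continue  # need both classes in truth
            po = (tp + tn) / n
            pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
            if pe == 1:
                continue
            expected = (po - pe) / (1 - pe)
            pred, truth = _labels_from_table(tp, fn, fp, tn)
            assert confusion_stats(pred, truth)["kappa"] == pytest.approx(expected)

    def test_multiclass_per_class_one_vs_rest(self):
        truth = ["R"] * 4 + ["IM"] * 3 + ["S"] * 3
        pred = ["R", "R", "IM", "R", "IM", "IM", "S", "S", "S", "R"]
        stats = confusion_stats(pred, truth)
        assert set(stats["sensitivity"]) == {"R", "IM", "S"}
        assert stats["sensitivity"]["R"] == pytest.approx(3 / 4)
        assert stats["specificity"]["R"] == pytest.approx(5 / 6)


class TestRegressionStats:
    def test_identity_and_mean_predictor(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert regression_stats(y, y)["r2"] == pytest.approx(1.0)
        assert regression_stats(np.full(4, y.mean()), y)["r2"] == pytest.approx(0.0)

    def test_hand_computed_rmse(self):
        """sqrt(0.06/3) = 0.1414..."""
        out = regression_stats([1.1, 1.9, 3.2], [1.0, 2.0, 3.0], space="linear")
        assert out["rmse"] == pytest.approx(np.sqrt(0.06 / 3))

    def test_zero_variance_flagged(self):
        out = regression_stats([1.0, 2.0], [3.0, 3.0])
        assert out["r2"] is None and "flag" in out

    def test_translation_invariance_of_r2(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=30)
        pred = obs + rng.normal(0, 0.3, 30)
        base = regression_stats(pred, obs)["r2"]
        shifted = regression_stats(pred + 5.0, obs + 5.0)["r2"]
        assert shifted == pytest.approx(base)

    def test_log_space_requires_positive(self):
        with pytest.raises(ValueError):
            regression_stats([1.0, -1.0], [1.0, 2.0], space="log10")


class TestFoldError:
    def test_exact_predictions_give_100_percent(self):
        y = np.array([0.5, 1.0, 2.0])
        assert fold_error_fraction(y, y, 2.0) == pytest.approx(100.0)

    def test_boundary_is_inclusive(self):
        assert fold_error_fraction([2.0], [1.0], 2.0) == pytest.approx(100.0)

    def test_mixed_set(self):
        """Only the exact pair is within 3-fold: 1/3 = 33.33%."""
        pred, obs = [1.0, 3.1, 1.0], [1.0, 1.0, 3.1]
        assert fold_error_fraction(pred, obs, 3.0) == pytest.approx(100 / 3)

    def test_nonpositive_named(self):
        with pytest.raises(ValueError, match="cmpd_b"):
            fold_errors([1.0, 0.0], [1.0, 1.0], ids=["cmpd_a", "cmpd_b"])

    @given(
        st.lists(
            st.tuples(st.floats(0.01, 100), st.floats(0.01, 100)),
            min_size=1,
            max_size=20,
        ),
        st.floats(1.01, 10),
        st.floats(0.0, 5.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetry_and_monotonicity(self, pairs, k, dk):
        """Fold-error fraction is symmetric in (pred, obs) and non-decreasing in k."""
        pred = [p for p, _ in pairs]
        obs = [o for _, o in pairs]
        assert fold_error_fraction(pred, obs, k) == pytest.approx(
            fold_error_fraction(obs, pred, k)
        )
        assert fold_error_fraction(pred, obs, k + dk) >= fold_error_fraction(pred, obs, k)


class TestRangeSplit:
    def test_all_above_cut_and_exact(self):
        y = np.array([2.0, 3.0, 5.0])
        report = range_split_report(y, y)
        high = report["by_predicted"]["high"]
        assert high["n"] == 3 and high["within_2fold_pct"] == pytest.approx(100.0)
        assert report["by_predicted"]["low"] == {"n": 0, "empty": True}

    def test_partition_sizes_as_constructed(self):
        pred = np.array([0.5, 0.6, 2.0, 3.0])
        obs = np.array([0.55, 0.5, 2.2, 2.5])
        report = range_split_report(pred, obs)
        assert report["by_predicted"]["high"]["n"] == 2
        assert report["by_predicted"]["low"]["n"] == 2
        assert report["by_observed"]["high"]["n"] == 2

    def test_cut_is_strictly_greater(self):
        constants = PhysiologyConstants()
        report = range_split_report(
            np.array([constants.clr_range_cut]), np.array([1.0]), constants
        )
        assert report["by_predicted"]["high"]["n"] == 0
        assert report["by_predicted"]["low"]["n"] == 1


class TestPairedComparison:
    def test_identical_series_flagged(self):
        out = paired_split_comparison([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert out["p_value"] is None and out["mean_difference"] == pytest.approx(0.0)

    def test_constant_shift_flagged(self):
        a = [0.5, 0.6, 0.7]
        out = paired_split_comparison(a, [x + 0.1 for x in a])
        assert out["p_value"] is None and "flag" in out

    def test_consistent_improvement_detected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.5, 0.05, 10)
        b = a + rng.normal(0.1, 0.01, 10)
        out = paired_split_comparison(a, b)
        assert out["p_value"] < 0.05 and out["mean_difference"] > 0


class TestReport:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            EvaluationReport(task="regression", n=5, fold_error_2x=80.0, fold_error_3x=50.0)
        with pytest.raises(ValueError):
            EvaluationReport(task="binary", n=5, kappa=1.5)
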