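import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coroscreen.evaluate import (ConfusionMatrix, bootstrap_interval, classification_metrics,
                                 confusion_at_cutoff, cutoff_sweep, grouped_report,
                                 metrics_report, pr_auc, roc_auc)


def brute_force_auc(probs, labels):
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum(float(p > q) + 0.5 * float(p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_basic_counts(self):
        cm = confusion_at_cutoff([0.9, 0.1], [1, 0], 0.5)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)

    def test_probability_at_cutoff_counts_positive(self):
        cm = confusion_at_cutoff([0.5], [0], 0.5)
        assert cm.fp == 1 and cm.tn == 0

    def test_cutoff_zero_makes_everything_positive(self):
        cm = confusion_at_cutoff([0.2, 0.8, 0.0], [1, 0, 1], 0.0)
        assert cm.tn == 0 and cm.fn == 0 and cm.n == 3

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_at_cutoff([0.5, 0.5], [1], 0.5)


class TestPointMetrics:
    def test_sensitivity(self):
        m = classification_metrics(ConfusionMatrix(tp=9, fp=0, tn=0, fn=1))
        assert np.isclose(m["sensitivity"], 0.9)

    def test_undefined_ppv_is_nan_not_zero(self):
        m = classification_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=5))
        assert np.isnan(m["ppv"])

    def test_f1_harmonic_mean(self):
        m = classification_metrics(ConfusionMatrix(tp=8, fp=2, tn=0, fn=2))
        assert np.isclose(m["ppv"], 0.8)
        assert np.isclose(m["sensitivity"], 0.8)
        assert np.isclose(m["f1"], 0.8)


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc(np.full(10, 0.3), [1] * 5 + [0] * 5) == 0.5

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            probs = np.round(rng.random(n), int(rng.integers(1, 3)))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert abs(roc_auc(probs, labels) - brute_force_auc(probs, labels)) < 1e-12

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        probs = rng.random(40)
        labels = np.r_[np.ones(15, int), np.zeros(25, int)]
        assert np.isclose(roc_auc(1 - probs, labels), 1 - roc_auc(probs, labels))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.random(30)
        labels = np.r_[np.ones(10, int), np.zeros(20, int)]
        transformed = probs**3 * 0.5 + 0.1 * probs   # strictly increasing on [0,1]
        transformed /= transformed.max() + 1e-9
        assert abs(roc_auc(probs, labels) - roc_auc(transformed, labels)) < 1e-12

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])

    def test_pr_auc_matches_average_precision(self):
        from sklearn.metrics import average_precision_score
        rng = np.random.default_rng(2)
        for _ in range(20):
            probs = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.sum() in (0, 30):
                continue
            assert abs(pr_auc(probs, labels)
                       - average_precision_score(labels, probs)) < 1e-12


class TestBootstrap:
    def test_single_iteration_degenerates(self):
        lo, hi = bootstrap_interval(roc_auc, [0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0],
                                    n_iter=1, seed=0)
        assert lo == hi

    def test_constant_metric_gives_point_interval(self):
        lo, hi = bootstrap_interval(lambda p, y: 0.7, [0.5, 0.6, 0.2], [1, 0, 1],
                                    n_iter=50, seed=0)
        assert lo == hi == 0.7

    def test_deterministic_given_seed(self):
        probs = np.random.default_rng(0).random(30)
        labels = np.r_[np.ones(10, int), np.zeros(20, int)]
        a = bootstrap_interval(roc_auc, probs, labels, 200, seed=7)
        b = bootstrap_interval(roc_auc, probs, labels, 200, seed=7)
        assert a == b

    def test_tolerance_band_brackets_roc_curve(self):
        probs = np.random.default_rng(1).random(60)
        labels = (probs + np.random.default_rng(2).normal(0, 0.3, 60) > 0.5).astype(int)
        grid, lo, hi = bootstrap_interval(roc_auc, probs, labels, 100, seed=0,
                                          kind="tolerance")
        assert grid.shape == lo.shape == hi.shape
        assert np.all(lo <= hi)
        assert np.all((0 <= lo) & (hi <= 1))


class TestCutoffSweep:
    def test_default_grid_has_nine_rows(self):
        df = cutoff_sweep([0.3, 0.6, 0.9], [0, 1, 1])
        assert len(df) == 9
        assert np.allclose(df.cutoff, np.arange(0.1, 0.95, 0.1))

    def test_sensitivity_and_specificity_monotone(self):
        rng = np.random.default_rng(3)
        probs = rng.random(200)
        labels = rng.integers(0, 2, 200)
        df = cutoff_sweep(probs, labels)
        assert np.all(np.diff(df.sensitivity) <= 1e-12)
        assert np.all(np.diff(df.specificity) >= -1e-12)


class TestGroupedReport:
    def _preds(self):
        rng = np.random.default_rng(4)
        n = 80
        y = rng.integers(0, 2, n)
        p = np.clip(0.6 * y + rng.normal(0.2, 0.2, n), 0, 1)
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        return pd.DataFrame({"ensemble_prob": p, "y_true": y, "sex": sex})

    def test_pooled_n_equals_sum_of_groups(self):
        df = self._preds()
        rep = grouped_report(df, "sex")
        assert rep["pooled"]["n"] == rep["F"]["n"] + rep["M"]["n"]

    def test_pooled_confusion_is_sum_of_group_confusions(self):
        df = self._preds()
        cms = {v: confusion_at_cutoff(sub.ensemble_prob, sub.y_true, 0.5)
               for v, sub in df.groupby("sex")}
        pooled = confusion_at_cutoff(df.ensemble_prob, df.y_true, 0.5)
        assert pooled.tp == sum(c.tp for c in cms.values())
        assert pooled.fp == sum(c.fp for c in cms.values())
        assert pooled.tn == sum(c.tn for c in cms.values())
        assert pooled.fn == sum(c.fn for c in cms.values())

    def test_identical_groups_get_identical_reports(self):
        df = pd.DataFrame({"ensemble_prob": [0.9, 0.2] * 4, "y_true": [1, 0] * 4,
                           "g": ["a", "a", "a", "a", "b", "b", "b", "b"]})
        rep = grouped_report(df, "g")
        assert rep["a"] == rep["b"]

    def test_single_class_group_flagged_nan_auc(self):
        df = pd.DataFrame({"ensemble_prob": [0.9, 0.8, 0.3, 0.7], "y_true": [1, 1, 0, 1],
                           "g": ["a", "a", "b", "b"]})
        rep = grouped_report(df, "g")
        assert np.isnan(rep["a"]["roc_auc"])

    def test_missing_group_column(self):
        with pytest.raises(ValueError):
            grouped_report(pd.DataFrame({"ensemble_prob": [0.5], "y_true": [1]}), "sex")


def test_metrics_report_reproducible_bitwise():
    probs = np.random.default_rng(5).random(50)
    labels = np.r_[np.ones(20, int), np.zeros(30, int)]
    a = metrics_report(probs, labels, n_boot=100, seed=3)
    b = metrics_report(probs, labels, n_boot=100, seed=3)
    assert a == b
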