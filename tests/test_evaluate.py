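import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from momentpls import evaluate
from momentpls.errors import UsageError
from momentpls.evaluate import (
    ConfusionCounts,
    confusion,
    five_fold_cv,
    loocv,
    metrics,
    proportional_validation,
)

from conftest import make_refined


class ConstantPipeline:
    """Predicts a fixed label for every sample (null classifier)."""

    def __init__(self, label=1):
        self.label = label

    def fit(self, matrix):
        return self

    def predict(self, matrix):
        return np.full(matrix.n_samples, self.label)


class NearestMeanPipeline:
    """Tiny genuine classifier: nearest class centroid on raw intensities."""

    def fit(self, matrix):
        X, y = matrix.intensities, matrix.labels
        self.mu_pos = X[:, y == 1].mean(axis=1)
        self.mu_neg = X[:, y == -1].mean(axis=1)
        return self

    def predict(self, matrix):
        X = matrix.intensities
        d_pos = np.linalg.norm(X - self.mu_pos[:, None], axis=0)
        d_neg = np.linalg.norm(X - self.mu_neg[:, None], axis=0)
        return np.where(d_pos <= d_neg, 1, -1)


class TestConfusion:
    def test_basic_counts(self):
        c = confusion([1, 1, -1], [1, 1, -1])
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 1, 0, 0)

    def test_flip_symmetry(self, rng):
        y = np.where(rng.random(50) < 0.5, 1, -1)
        p = np.where(rng.random(50) < 0.5, 1, -1)
        c, cf = confusion(y, p), confusion(y, -p)
        assert (cf.TP, cf.FN, cf.TN, cf.FP) == (c.FN, c.TP, c.FP, c.TN)

    def test_random_pair_matches_brute_force(self, rng):
        y = np.where(rng.random(200) < 0.6, 1, -1)
        p = np.where(rng.random(200) < 0.4, 1, -1)
        c = confusion(y, p)
        tally = {"TP": 0, "FN": 0, "TN": 0, "FP": 0}
        for yt, yp in zip(y, p):
            if yt == 1:
                tally["TP" if yp == 1 else "FN"] += 1
            else:
                tally["TN" if yp == -1 else "FP"] += 1
        assert (c.TP, c.FN, c.TN, c.FP) == tuple(tally.values())
        assert c.total == 200

    def test_length_mismatch(self):
        with pytest.raises(UsageError):
            confusion([1, -1], [1])


class TestMetrics:
    def test_one_control_misclassified_of_216(self):
        """121/121 cancers and 94/95 controls correct: the headline
        leave-one-out outcome for a 95-control/121-cancer cohort."""
        ms = metrics(ConfusionCounts(TP=121, FN=0, TN=94, FP=1))
        assert round(ms.Ac, 4) == 0.9954
        assert round(ms.CC, 4) == 0.9906
        assert round(ms.Sn, 4) == 1.0000
        assert round(ms.Sp, 4) == 0.9895

    def test_perfect_classification(self):
        ms = metrics(ConfusionCounts(TP=10, FN=0, TN=10, FP=0))
        assert ms.Ac == ms.Sn == ms.Sp == ms.CC == 1.0

    def test_random_counts_match_formulas(self, rng):
        for _ in range(20):
            tp, fn, tn, fp = [int(v) for v in rng.integers(1, 50, size=4)]
            ms = metrics(ConfusionCounts(tp, fn, tn, fp))
            assert ms.Ac == pytest.approx((tp + tn) / (tp + fn + tn + fp))
            assert ms.Sn == pytest.approx(tp / (tp + fn))
            assert ms.Sp == pytest.approx(tn / (tn + fp))
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            assert ms.CC == pytest.approx((tp * tn - fp * fn) / math.sqrt(denom))

    def test_cc_zero_when_factor_vanishes(self):
        # all predictions positive: TN + FN column factor is 0
        ms = metrics(ConfusionCounts(TP=5, FN=0, TN=0, FP=5))
        assert ms.CC == 0.0

    def test_no_positives_presented_is_error(self):
        with pytest.raises(UsageError, match="sensitivity"):
            metrics(ConfusionCounts(TP=0, FN=0, TN=5, FP=1))

    @given(tp=st.integers(1, 40), tn=st.integers(1, 40))
    def test_cc_is_one_iff_no_errors(self, tp, tn):
        assert metrics(ConfusionCounts(tp, 0, tn, 0)).CC == pytest.approx(1.0)

    @given(
        tp=st.integers(0, 30), fn=st.integers(0, 30),
        tn=st.integers(0, 30), fp=st.integers(0, 30),
    )
    def test_accuracy_is_prevalence_weighted_mean_of_sn_sp(self, tp, fn, tn, fp):
        n_pos, n_neg = tp + fn, tn + fp
        if n_pos == 0 or n_neg == 0:
            return
        ms = metrics(ConfusionCounts(tp, fn, tn, fp))
        expected = (n_pos * ms.Sn + n_neg * ms.Sp) / (n_pos + n_neg)
        assert ms.Ac == pytest.approx(expected)


class TestFiveFoldCV:
    def test_null_classifier_metrics(self, rng):
        m = make_refined(rng.normal(size=(20, 40)), labels=[1] * 20 + [-1] * 20)
        report = five_fold_cv(lambda: ConstantPipeline(1), m, repeats=5, seed=0)
        assert report.mean["Ac"] == pytest.approx(0.5)
        assert report.mean["CC"] == pytest.approx(0.0)
        assert report.mean["Sn"] == pytest.approx(1.0)
        assert report.mean["Sp"] == pytest.approx(0.0)

    def test_separated_data_classified_well(self, rng):
        vals = rng.normal(0, 1, size=(30, 40))
        labels = np.array([1] * 20 + [-1] * 20)
        vals[:5, labels == 1] += 5.0
        m = make_refined(vals, labels=labels)
        report = five_fold_cv(lambda: NearestMeanPipeline(), m, repeats=5, seed=0)
        assert report.mean["Ac"] >= 0.95

    def test_same_seed_identical_reports(self, rng):
        m = make_refined(rng.normal(size=(10, 30)), labels=[1] * 15 + [-1] * 15)
        r1 = five_fold_cv(lambda: NearestMeanPipeline(), m, repeats=4, seed=9)
        r2 = five_fold_cv(lambda: NearestMeanPipeline(), m, repeats=4, seed=9)
        assert r1.per_repeat == r2.per_repeat
        assert r1.mean == r2.mean and r1.sd == r2.sd

    def test_class_too_small_rejected(self, rng):
        m = make_refined(rng.normal(size=(5, 7)), labels=[1] * 3 + [-1] * 4)
        with pytest.raises(UsageError, match="per class"):
            five_fold_cv(lambda: ConstantPipeline(), m, repeats=1, seed=0)

    def test_sd_uses_sample_convention(self, rng):
        m = make_refined(rng.normal(size=(8, 30)), labels=[1] * 15 + [-1] * 15)
        report = five_fold_cv(lambda: NearestMeanPipeline(), m, repeats=6, seed=1)
        acs = np.array([r.Ac for r in report.per_repeat])
        assert report.sd["Ac"] == pytest.approx(acs.std(ddof=1))


class TestProportionalValidation:
    def test_split_sizes(self, rng):
        m = make_refined(rng.normal(size=(6, 20)), labels=[1] * 10 + [-1] * 10)

        seen = []

        class CountingPipeline(ConstantPipeline):
            def fit(self, matrix):
                seen.append(
                    (int((matrix.labels == 1).sum()), int((matrix.labels == -1).sum()))
                )
                return self

        proportional_validation(CountingPipeline, m, train_fraction=0.8,
                                repeats=3, seed=0)
        assert seen == [(8, 8)] * 3

    def test_null_classifier_cc_zero(self, rng):
        m = make_refined(rng.normal(size=(6, 30)), labels=[1] * 15 + [-1] * 15)
        report = proportional_validation(
            lambda: ConstantPipeline(-1), m, repeats=4, seed=0
        )
        assert report.mean["CC"] == pytest.approx(0.0)

    def test_determinism(self, rng):
        m = make_refined(rng.normal(size=(6, 30)), labels=[1] * 15 + [-1] * 15)
        r1 = proportional_validation(lambda: NearestMeanPipeline(), m, repeats=3, seed=5)
        r2 = proportional_validation(lambda: NearestMeanPipeline(), m, repeats=3, seed=5)
        assert r1.per_repeat == r2.per_repeat


class TestLOOCV:
    def test_counts_sum_to_n(self, rng):
        m = make_refined(rng.normal(size=(5, 12)), labels=[1] * 6 + [-1] * 6)
        ms, table = loocv(lambda: ConstantPipeline(1), m)
        assert len(table) == 12

    def test_separable_data_perfect(self, rng):
        vals = rng.normal(0, 1, size=(10, 40))
        labels = np.array([1] * 20 + [-1] * 20)
        vals[:, labels == 1] += 8.0
        m = make_refined(vals, labels=labels)
        ms, _ = loocv(lambda: NearestMeanPipeline(), m)
        assert ms.Ac == 1.0

    def test_held_out_prediction_ignores_own_label(self, rng):
        """A memorising classifier cannot see the held-out sample's label."""

        class MemorisingPipeline:
            def fit(self, matrix):
                self.majority = 1 if (matrix.labels == 1).sum() >= (
                    matrix.labels == -1
                ).sum() else -1
                return self

            def predict(self, matrix):
                return np.full(matrix.n_samples, self.majority)

        # 2 positives, 1 negative: leaving out a positive ties 1-1 (-> +1),
        # leaving out the negative trains on 2 positives (-> +1)
        m = make_refined(rng.normal(size=(4, 3)), labels=[1, 1, -1])
        _, table = loocv(lambda: MemorisingPipeline(), m)
        assert [pred for _, _, pred in table] == [1, 1, 1]

    def test_repeated_calls_identical(self, rng):
        m = make_refined(rng.normal(size=(6, 14)), labels=[1] * 7 + [-1] * 7)
        out1 = loocv(lambda: NearestMeanPipeline(), m)
        out2 = loocv(lambda: NearestMeanPipeline(), m)
        assert out1 == out2

    def test_too_few_samples(self, rng):
        m = make_refined(rng.normal(size=(3, 2)), labels=[1, -1])
        with pytest.raises(UsageError):
            loocv(lambda: ConstantPipeline(), m)
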