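"""Metric, statistical-test, calibration and ablation oracles."""

import math

import numpy as np
import pytest

from mmfde.evaluation import (
    ConfusionCounts,
    bonferroni,
    bootstrap_ci,
    calibration_report,
    classification_metrics,
    five_by_two_cv_ttest,
    mcnemar,
    mcnemar_statistic,
    ranking_metrics,
    ablation,
)
from mmfde.fusion import ConfidenceMatrix, DistanceWeights, FusionResult, fuse


def make_results(mu_max, correct_label, predicted=None):
    """Construct FusionResults with a chosen maximum membership and label."""
    from mmfde.fusion import confidence_level, fuzzy_score

    out = []
    for m, lbl in zip(mu_max, predicted if predicted is not None else correct_label):
        if lbl == 1:
            mu_pos, mu_neg = m, m / 2
        else:
            mu_pos, mu_neg = m / 2, m
        out.append(
            FusionResult(
                lambda_pos=-math.log(max(mu_pos, 1e-12)),
                lambda_neg=-math.log(max(mu_neg, 1e-12)),
                mu_pos=mu_pos,
                mu_neg=mu_neg,
                fuzzy_score=fuzzy_score(mu_pos, mu_neg),
                label=int(lbl),
                confidence_level=confidence_level(max(mu_pos, mu_neg)),
            )
        )
    return out


class TestClassificationMetrics:
    def test_hand_arithmetic_example(self):
        rep = classification_metrics(ConfusionCounts(TP=3, TN=4, FP=1, FN=2))
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.6)
        assert rep.f1 == pytest.approx(0.6667, abs=5e-5)

    def test_perfect_classifier(self):
        rep = classification_metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (1, 1, 1, 1)

    def test_undefined_precision_marker(self):
        rep = classification_metrics(ConfusionCounts(TP=0, TN=3, FP=0, FN=2))
        assert math.isnan(rep.precision)
        assert rep.accuracy == pytest.approx(0.6)

    def test_against_confusion_count_oracle(self, rng):
        """Formulas agree with independent counting on random vectors."""
        for _ in range(200):
            n = rng.integers(4, 40)
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            counts = ConfusionCounts.from_predictions(p, y)
            # independent oracle: direct pair counting
            tp = sum(1 for a, b in zip(p, y) if a == 1 and b == 1)
            fp = sum(1 for a, b in zip(p, y) if a == 1 and b == 0)
            fn = sum(1 for a, b in zip(p, y) if a == 0 and b == 1)
            tn = n - tp - fp - fn
            assert (counts.TP, counts.TN, counts.FP, counts.FN) == (tp, tn, fp, fn)
            rep = classification_metrics(counts)
            assert rep.accuracy == pytest.approx((tp + tn) / n)
            if tp + fp:
                assert rep.precision == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert rep.recall == pytest.approx(tp / (tp + fn))
            if 2 * tp + fp + fn:
                assert rep.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))


class TestRankingMetrics:
    def test_perfect_separation(self):
        auc, pr = ranking_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0 and pr == 1.0

    def test_all_ties_give_half_auc(self):
        auc, _ = ranking_metrics([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_auc_equals_concordant_pair_fraction(self, rng):
        scores = rng.uniform(size=6)
        labels = np.array([0, 1, 0, 1, 1, 0])
        auc, _ = ranking_metrics(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        conc = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert auc == pytest.approx(conc / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ranking_metrics([0.1, 0.9], [1, 1])


class TestMcNemar:
    def test_corrected_statistic_hand_arithmetic(self):
        assert mcnemar_statistic(10, 2) == pytest.approx(4.0833, abs=5e-5)

    def test_equal_discordants_floor_at_zero(self):
        assert mcnemar_statistic(3, 3) == 0.0

    def test_identical_predictions_degenerate(self):
        res = mcnemar([1, 0, 1], [1, 0, 1], [1, 1, 0])
        assert res.degenerate and res.p == 1.0

    def test_exact_branch_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        y = np.zeros(30, dtype=int)
        a = np.array([0] * 20 + [1] * 10)   # a wrong on 10
        b = np.array([0] * 28 + [1] * 2)    # b wrong on 2, overlapping a
        res = mcnemar(a, b, y)
        assert res.exact
        b_count, c_count = res.b, res.c
        table = [[0, b_count], [c_count, 0]]
        sm = sm_mcnemar(table, exact=True)
        assert res.p == pytest.approx(sm.pvalue)

    def test_large_sample_chi2_branch(self, rng):
        y = np.zeros(200, dtype=int)
        a = (rng.uniform(size=200) < 0.3).astype(int)
        b = (rng.uniform(size=200) < 0.3).astype(int)
        res = mcnemar(a, b, y)
        if res.b + res.c >= 25:
            from scipy import stats

            assert res.statistic == pytest.approx(
                mcnemar_statistic(res.b, res.c)
            )
            assert res.p == pytest.approx(stats.chi2.sf(res.statistic, 1))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            mcnemar([1, 0], [1], [1, 0])


class FixedAccuracyClassifier:
    """Deterministic stub: memorises a fixed error rate pattern."""

    def __init__(self, flip_every):
        self.flip_every = flip_every

    def fit(self, X, y):
        self.y_ = np.asarray(y)
        return self

    def predict(self, X):
        n = len(X)
        preds = np.resize(self.y_, n).copy()
        preds[:: self.flip_every] = 1 - preds[:: self.flip_every]
        return preds


class TestFiveByTwoCV:
    @pytest.fixture()
    def xy(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] + rng.normal(scale=0.5, size=80) > 0).astype(int)
        import pandas as pd

        return pd.DataFrame(X), y

    def test_identical_builders_degenerate(self, xy):
        X, y = xy
        res = five_by_two_cv_ttest(X, y, lambda: FixedAccuracyClassifier(3),
                                   lambda: FixedAccuracyClassifier(3), seed=1)
        assert res.degenerate_variance and res.p == 1.0

    @staticmethod
    def weak():
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(max_depth=1, random_state=0)

    @staticmethod
    def strong():
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(max_depth=5, random_state=0)

    def test_antisymmetry(self, xy):
        X, y = xy
        r_ab = five_by_two_cv_ttest(X, y, self.strong, self.weak, seed=2)
        r_ba = five_by_two_cv_ttest(X, y, self.weak, self.strong, seed=2)
        assert r_ab.t == pytest.approx(-r_ba.t)
        assert r_ab.p == pytest.approx(r_ba.p)

    def test_statistic_recomputed_from_stored_differences(self, xy):
        """Straight-line transcription of the 5x2cv formula on the stored
        fold differences reproduces the statistic."""
        from scipy import stats

        X, y = xy
        res = five_by_two_cv_ttest(X, y, self.strong, self.weak, seed=3)
        assert not res.degenerate_variance
        d = res.differences
        s2 = [
            (d[r, 0] - d[r].mean()) ** 2 + (d[r, 1] - d[r].mean()) ** 2
            for r in range(5)
        ]
        t = d[0, 0] / math.sqrt(sum(s2) / 5)
        assert res.t == pytest.approx(t)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), 5))


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,k,expected", [(0.05, 8, 0.00625), (0.05, 1, 0.05), (0.10, 4, 0.025)]
    )
    def test_adjustment(self, alpha, k, expected):
        assert bonferroni(alpha, k) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)


class TestBootstrapCI:
    @staticmethod
    def accuracy(scores, labels):
        return float(np.mean((scores >= 0.5) == labels))

    def test_degenerate_distribution(self):
        lo, hi = bootstrap_ci(self.accuracy, np.ones(20), np.ones(20, dtype=int),
                              B=100, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_seed_determinism(self):
        scores = np.linspace(0, 1, 50)
        labels = (scores > 0.4).astype(int)
        ci1 = bootstrap_ci(self.accuracy, scores, labels, B=200, seed=7)
        ci2 = bootstrap_ci(self.accuracy, scores, labels, B=200, seed=7)
        assert ci1 == ci2

    def test_matches_independent_resample_stream(self):
        """With the same seeded index stream, an independent transcription
        of the percentile bootstrap gives identical endpoints."""
        rng_scores = np.random.default_rng(11)
        scores = rng_scores.uniform(size=30)
        labels = (scores + rng_scores.normal(scale=0.2, size=30) > 0.5).astype(int)
        B, seed = 50, 3
        got = bootstrap_ci(self.accuracy, scores, labels, B=B, seed=seed)
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(B):
            idx = rng.integers(0, 30, size=30)
            vals.append(self.accuracy(scores[idx], labels[idx]))
        lo, hi = np.percentile(vals, [2.5, 97.5])
        assert got == (pytest.approx(lo), pytest.approx(hi))

    def test_interval_narrows_with_sample_size(self):
        widths = []
        for n in (50, 200, 1000):
            rng = np.random.default_rng(42)
            labels = rng.integers(0, 2, n)
            scores = np.where(rng.uniform(size=n) < 0.8, labels, 1 - labels).astype(float)
            w = []
            for seed in range(5):
                lo, hi = bootstrap_ci(self.accuracy, scores, labels, B=200, seed=seed)
                w.append(hi - lo)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]


class TestCalibrationReport:
    def test_perfectly_confident_and_correct(self):
        results = make_results([1.0] * 10, [1] * 10)
        rep = calibration_report(results, [1] * 10)
        assert rep.ece == pytest.approx(0.0)

    def test_single_bin_worked_case(self):
        """All confidences 0.9 with half correct: ECE = |0.5 - 0.9| = 0.4."""
        results = make_results([0.9] * 10, [1] * 10, predicted=[1] * 10)
        labels = [1] * 5 + [0] * 5
        rep = calibration_report(results, labels)
        assert rep.ece == pytest.approx(0.4)

    def test_level_distribution_sums_to_one(self, rng):
        mu = rng.uniform(0.3, 1.0, 40)
        results = make_results(mu, rng.integers(0, 2, 40))
        rep = calibration_report(results, rng.integers(0, 2, 40))
        assert sum(rep.level_distribution.values()) == pytest.approx(1.0)
        assert sum(rep.bin_weight) == pytest.approx(1.0)

    def test_worked_fixture_level_distribution(self, worked_example):
        from mmfde.fusion import confidence_level, fuzzy_score

        results = make_results(
            [max(p, n) for p, n in zip(worked_example.mu_pos, worked_example.mu_neg)],
            worked_example.predictions,
        )
        rep = calibration_report(results, list(worked_example.labels))
        assert rep.level_distribution == {
            "VeryHigh": pytest.approx(0.4),
            "High": pytest.approx(0.4),
            "Moderate": pytest.approx(0.2),
        }

    def test_self_calibrated_predictions_have_small_ece(self):
        """When per-sample accuracy equals confidence, ECE tends to zero."""
        rng = np.random.default_rng(0)
        n = 10_000
        conf = rng.uniform(0.5, 1.0, n)
        labels = np.ones(n, dtype=int)
        correct = rng.uniform(size=n) < conf
        predicted = np.where(correct, 1, 0)
        results = make_results(conf, labels, predicted=predicted)
        rep = calibration_report(results, labels)
        assert rep.ece < 0.03

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError, match="no fusion results"):
            calibration_report([], [])

    def test_fuzzy_score_axis_switch(self, rng):
        results = make_results(rng.uniform(0.5, 1, 20), rng.integers(0, 2, 20))
        rep = calibration_report(results, rng.integers(0, 2, 20), axis="fuzzy_score")
        assert rep.axis == "fuzzy_score"
        with pytest.raises(ValueError, match="axis"):
            calibration_report(results, np.zeros(20), axis="nope")


class TestAblation:
    W = DistanceWeights(0.3, 0.3, 0.2, 0.2)

    @pytest.fixture()
    def matrix_labels(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, 60)
        P = np.clip(labels[:, None] * 0.6 + rng.uniform(0, 0.4, (60, 4)), 0, 1)
        return ConfidenceMatrix(P), labels

    def test_dropping_zero_weight_metric_is_noop(self, matrix_labels):
        matrix, labels = matrix_labels
        w = DistanceWeights(0.5, 0.5, 0.0, 0.0)
        res = ablation(matrix, labels, w, beta=2.0, metric_to_drop="cosine")
        assert res.report.accuracy == res.full_report.accuracy
        assert res.delta_accuracy == 0.0

    def test_proportional_redistribution(self, matrix_labels):
        matrix, labels = matrix_labels
        res = ablation(matrix, labels, self.W, beta=2.0, metric_to_drop="cosine")
        assert np.allclose(res.weights.as_array(), [0.375, 0.375, 0.0, 0.25])

    def test_all_single_metric_drops_complete(self, matrix_labels):
        matrix, labels = matrix_labels
        for metric in ("euclidean", "manhattan", "cosine", "chebyshev"):
            res = ablation(matrix, labels, self.W, beta=2.0, metric_to_drop=metric)
            assert 0 <= res.report.accuracy <= 1
            assert np.isfinite(res.delta_accuracy)

    def test_dropping_total_weight_rejected(self, matrix_labels):
        matrix, labels = matrix_labels
        with pytest.raises(ValueError, match="all the weight"):
            ablation(matrix, labels, DistanceWeights(1, 0, 0, 0), 2.0, "euclidean")
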