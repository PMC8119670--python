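"""Confusion matrix, balanced accuracy, ROC/AUC, bootstrap CI, correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from livedead import evaluation


def _labels(bits):
    return np.array(["live" if b else "dead" for b in bits])


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        truth = _labels([1, 1, 0, 0])
        cm = evaluation.confusion_matrix(truth, truth)
        assert cm[0, 1] == cm[1, 0] == 0
        assert cm[0, 0] == 2 and cm[1, 1] == 2

    def test_constant_prediction_fills_one_column(self):
        truth = _labels([1, 0, 1, 0])
        pred = _labels([1, 1, 1, 1])
        cm = evaluation.confusion_matrix(pred, truth)
        assert cm[:, 1].sum() == 0 and cm[:, 0].sum() == 4

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                    max_size=80))
    def test_matches_brute_force_tally(self, pairs):
        pred = _labels([p for p, _ in pairs])
        truth = _labels([t for _, t in pairs])
        cm = evaluation.confusion_matrix(pred, truth)
        classes = ("live", "dead")
        for i, t in enumerate(classes):
            for j, p in enumerate(classes):
                assert cm[i, j] == sum(
                    1 for (pp, tt) in zip(pred, truth) if tt == t and pp == p)
        assert cm.sum() == len(pairs)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluation.confusion_matrix(_labels([1]), _labels([1, 0]))


class TestBalancedAccuracy:
    @pytest.mark.parametrize("cm,expected", [
        (np.array([[10, 0], [0, 5]]), 1.0),
        (np.array([[7, 0], [3, 0]]), 0.5),  # everything predicted live
        (np.array([[90, 10], [30, 70]]), 0.8),
    ])
    def test_known_matrices(self, cm, expected):
        assert evaluation.balanced_accuracy(cm) == pytest.approx(expected)

    def test_empty_truth_class_rejected(self):
        with pytest.raises(ValueError):
            evaluation.balanced_accuracy(np.array([[0, 0], [3, 7]]))

    def test_label_swap_symmetry(self):
        # swapping both rows and columns (relabeling the classes) leaves
        # the mean per-class recall unchanged
        cm = np.array([[40, 9], [13, 38]])
        swapped = cm[::-1, ::-1]
        assert evaluation.balanced_accuracy(cm) == pytest.approx(
            evaluation.balanced_accuracy(swapped))


def _auc_oracle(scores, truth):
    """All-pairs concordance: P(live outscores dead), ties count one half."""
    live = scores[truth == "live"]
    dead = scores[truth == "dead"]
    wins = 0.0
    for a in live:
        for b in dead:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(live) * len(dead))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truth = _labels([1, 1, 0, 0])
        auc, fpr, tpr = evaluation.roc_auc(scores, truth)
        assert auc == 1.0

    def test_all_ties_give_half(self):
        scores = np.full(10, 0.5)
        truth = _labels([1, 0] * 5)
        auc, _, _ = evaluation.roc_auc(scores, truth)
        assert auc == pytest.approx(0.5)

    @settings(max_examples=15)
    @given(st.integers(0, 10_000))
    def test_matches_pairwise_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        truth = _labels(rng.integers(0, 2, size=n))
        if len(set(truth)) < 2:
            return
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        auc, _, _ = evaluation.roc_auc(scores, truth)
        assert auc == pytest.approx(_auc_oracle(scores, truth), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        truth = _labels(rng.integers(0, 2, size=100))
        scores = rng.random(100)
        a1, _, _ = evaluation.roc_auc(scores, truth)
        a2, _, _ = evaluation.roc_auc(np.exp(5 * scores), truth)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluation.roc_auc(np.array([0.1, 0.9]), _labels([1, 1]))


def _ba_metric(pred, truth):
    return evaluation.balanced_accuracy(evaluation.confusion_matrix(pred, truth))


class TestBootstrapCi:
    def test_zero_variance_metric_collapses(self):
        truth = _labels([1] * 20 + [0] * 20)
        lo, hi = evaluation.bootstrap_ci(_ba_metric, truth, truth,
                                         n_boot=100, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        truth = _labels(rng.integers(0, 2, size=120))
        pred = truth.copy()
        flip = rng.random(120) < 0.2
        pred[flip] = np.where(pred[flip] == "live", "dead", "live")
        point = _ba_metric(pred, truth)
        lo, hi = evaluation.bootstrap_ci(_ba_metric, pred, truth,
                                         n_boot=500, seed=2)
        assert lo <= point <= hi

    def test_coverage_on_simulated_test_sets(self):
        # known generating accuracy 0.8 per class; the 95% percentile
        # interval should cover it in >= 90% of simulations
        rng = np.random.default_rng(3)
        target = 0.8
        covered = 0
        n_sim = 200
        for _ in range(n_sim):
            truth = _labels(rng.integers(0, 2, size=100))
            correct = rng.random(100) < target
            pred = np.where(correct, truth,
                            np.where(truth == "live", "dead", "live"))
            lo, hi = evaluation.bootstrap_ci(_ba_metric, pred, truth,
                                             n_boot=200,
                                             seed=int(rng.integers(2**31)))
            covered += lo <= target <= hi
        assert covered / n_sim >= 0.90

    def test_small_samples_rejected(self):
        truth = _labels([1, 0] * 5)
        with pytest.raises(ValueError):
            evaluation.bootstrap_ci(_ba_metric, truth, truth, n_boot=10)


class TestFluorescenceScoreCorrelation:
    def test_exact_negative_linear_relation(self):
        fluor = np.linspace(100, 900, 50)
        scores = -0.001 * fluor + 1.0
        r, p = evaluation.fluorescence_score_correlation(fluor, scores)
        assert r == pytest.approx(-1.0)

    def test_independent_vectors_near_zero_with_uniformish_p(self):
        rng = np.random.default_rng(4)
        rs, ps = [], []
        for _ in range(30):
            x = rng.random(1000)
            y = rng.random(1000)
            r, p = evaluation.fluorescence_score_correlation(x, y)
            rs.append(r)
            ps.append(p)
        assert np.median(np.abs(rs)) < 0.1
        # p-values approximately uniform under the null
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.random(200)
        y = 0.3 * x + rng.random(200)
        r, _ = evaluation.fluorescence_score_correlation(x, y)
        oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            evaluation.fluorescence_score_correlation(
                np.ones(10), np.arange(10.0))
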