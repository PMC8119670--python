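"""Evaluation surface for trained live/dead classifiers.

Covers the metrics used to compare patch classifiers under class imbalance:
the confusion matrix, balanced accuracy (mean of per-class recalls, which a
majority-class-biased model cannot inflate) with a percentile-bootstrap
confidence interval, the ROC curve and its AUC, and the Pearson correlation
between each test patch's mean fluorescence and its classifier score. With
scores defined as the live-class probability, that correlation is expected
to be negative: high propidium-iodide fluorescence marks dead cells, which
should receive low live scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["EvalReport", "confusion_matrix", "balanced_accuracy", "roc_auc",
           "bootstrap_ci", "fluorescence_score_correlation", "evaluate"]

CLASSES = ("live", "dead")


@dataclass
class EvalReport:
    confusion: np.ndarray
    balanced_accuracy: float
    balanced_accuracy_ci: tuple[float, float]
    auc: float
    pearson_r: float
    pearson_p: float
    n_test: int

    def to_json(self) -> str:
        return json.dumps({
            "confusion": self.confusion.tolist(),
            "balanced_accuracy": self.balanced_accuracy,
            "balanced_accuracy_ci": list(self.balanced_accuracy_ci),
            "auc": self.auc,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "n_test": self.n_test,
        }, indent=2)


def _check_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    bad = set(arr.tolist()) - set(CLASSES)
    if bad:
        raise ValueError(f"labels must be in {CLASSES}, got extra {sorted(bad)}")
    return arr


def confusion_matrix(pred, truth) -> np.ndarray:
    """2x2 counts by (truth row, prediction column), live first."""
    pred = _check_labels(pred)
    truth = _check_labels(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    cm = np.zeros((2, 2), dtype=int)
    for i, t in enumerate(CLASSES):
        for j, p in enumerate(CLASSES):
            cm[i, j] = int(np.sum((truth == t) & (pred == p)))
    return cm


def balanced_accuracy(confusion: np.ndarray) -> float:
    """Mean of per-class recalls from a 2x2 confusion matrix."""
    cm = np.asarray(confusion, dtype=float)
    row_sums = cm.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("every truth class needs at least one sample")
    recalls = np.diag(cm) / row_sums
    return float(recalls.mean())


def roc_auc(scores, truth):
    """AUC of live-probability scores plus the ROC curve points.

    AUC equals the probability that a randomly chosen live patch outscores a
    randomly chosen dead one, ties counting one half. Returns
    ``(auc, fpr, tpr)``.
    """
    truth = _check_labels(truth)
    scores = np.asarray(scores, dtype=float)
    y = (truth == "live").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute ROC/AUC")
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores)
    return auc, fpr, tpr


def bootstrap_ci(metric_fn, pred, truth, n_boot: int = 2000,
                 level: float = 0.95, seed: int = 0,
                 max_redraws: int = 100) -> tuple[float, float]:
    """Percentile bootstrap CI of ``metric_fn(pred, truth)`` over resampled
    test indices.

    Resamples producing a single truth class are redrawn (the metric is
    undefined there), up to ``max_redraws`` extra attempts per replicate;
    hitting the cap raises a warning and keeps the last resample's metric if
    computable.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    n = len(truth)
    if n < 30:
        raise ValueError(f"bootstrap CI needs n >= 30, got {n}")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(truth[idx])) > 1:
                break
        else:
            warnings.warn("degenerate bootstrap resamples persisted to the cap")
        vals.append(metric_fn(pred[idx], truth[idx]))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def fluorescence_score_correlation(mean_fluorescence, scores) -> tuple[float, float]:
    """Pearson r (with two-sided p) between mean fluorescence and live score."""
    x = np.asarray(mean_fluorescence, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def evaluate(scores: np.ndarray, truth, mean_fluor=None, n_boot: int = 2000,
             seed: int = 0) -> EvalReport:
    """Full report from live-probability scores and truth labels."""
    truth = _check_labels(truth)
    scores = np.asarray(scores, dtype=float)
    pred = np.where(scores >= 0.5, "live", "dead")
    cm = confusion_matrix(pred, truth)
    ba = balanced_accuracy(cm)
    ci = bootstrap_ci(
        lambda p, t: balanced_accuracy(confusion_matrix(p, t)),
        pred, truth, n_boot=n_boot, seed=seed,
    )
    auc, _, _ = roc_auc(scores, truth)
    if mean_fluor is not None:
        r, pval = fluorescence_score_correlation(mean_fluor, scores)
    else:
        r, pval = float("nan"), float("nan")
    return EvalReport(confusion=cm, balanced_accuracy=ba,
                      balanced_accuracy_ci=ci, auc=auc,
                      pearson_r=r, pearson_p=pval, n_test=len(truth))
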