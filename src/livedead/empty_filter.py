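"""Detection and removal of empty / unusable bright-field patches.

Patches that capture no cells (or only out-of-focus content) carry no signal
for the classifier and are curated out before weak labeling. Each patch is
summarized by a deep feature vector — the globally average-pooled output of
the last convolutional layer of a frozen backbone — and a support vector
machine trained on small manually labeled sets of empty and properly
captured patches separates the two.

The default detector is a supervised two-class SVM with an RBF kernel,
since labeled examples of both classes are available; a one-class
(novelty-detection) mode fitted on non-empty features only is available via
``SVMParams(mode="one_class")``.

The shipped :class:`RandomConvFeatureExtractor` is a fixed-seed,
random-weight convolutional feature extractor with the same
224x224 -> pooled-vector contract as a pretrained network's last
convolutional block; any frozen backbone exposing ``feature_dim`` and
``features(batch)`` (e.g. a 512-feature residual network) drops in for
real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, OneClassSVM

from . import nn
from .patches import PatchPair

__all__ = ["FeatureVector", "EmptyDetector", "SVMParams",
           "RandomConvFeatureExtractor", "extract_features",
           "fit_empty_detector", "f1_score", "filter_patches"]


@dataclass(frozen=True)
class FeatureVector:
    patch_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite feature values for {self.patch_id}")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SVMParams:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    nu: float = 0.1  # one-class mode only
    mode: str = "two_class"  # "two_class" | "one_class"


@dataclass
class EmptyDetector:
    """A fitted SVM over backbone features; predicts True for empty patches."""

    svm: object
    feature_dim: int
    params: SVMParams
    n_empty_train: int = 0
    n_nonempty_train: int = 0

    def predict_empty(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != self.feature_dim:
            raise ValueError(
                f"feature length {x.shape[1]} does not match detector's "
                f"training length {self.feature_dim}"
            )
        if self.params.mode == "one_class":
            # fitted on non-empty features: outliers (-1) are empty
            return self.svm.predict(x) == -1
        return self.svm.predict(x) == 1


class RandomConvFeatureExtractor:
    """Frozen random-weight convolutional feature extractor.

    Three strided conv/ReLU blocks followed by global average pooling map a
    224x224 patch to a fixed-length vector. Weights are drawn once from the
    seed and never updated, so features are deterministic. Random
    convolutional features preserve enough texture/intensity structure to
    separate background-only patches from patches containing cells.
    """

    def __init__(self, seed: int = 0, feature_dim: int = 64):
        rng = np.random.default_rng(seed)
        self.feature_dim = feature_dim
        self.net = nn.Sequential([
            nn.Conv2d(1, 16, kernel=5, stride=4, rng=rng), nn.ReLU(),
            nn.Conv2d(16, 32, kernel=3, stride=2, rng=rng), nn.ReLU(),
            nn.Conv2d(32, feature_dim, kernel=3, stride=2, rng=rng), nn.ReLU(),
            nn.GlobalAvgPool(),
        ])

    def features(self, batch: np.ndarray) -> np.ndarray:
        x = np.asarray(batch, dtype=np.float64)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        return self.net.forward(x)


def extract_features(patch: np.ndarray, backbone,
                     patch_id: str = "") -> FeatureVector:
    """Pooled last-convolutional-layer features of one 8-bit 224x224 patch."""
    arr = np.asarray(patch)
    if arr.shape != (224, 224):
        raise ValueError(f"expected a 224x224 patch, got {arr.shape}")
    vec = backbone.features(arr.astype(np.float64) / 255.0)[0]
    if vec.shape[0] != backbone.feature_dim:
        raise AssertionError("backbone returned an unexpected feature length")
    return FeatureVector(patch_id=patch_id, values=vec)


def _stack(features: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.atleast_2d(features)
    return np.vstack([f.values for f in features])


def fit_empty_detector(empty_features, nonempty_features,
                       params: SVMParams | None = None) -> EmptyDetector:
    """Fit the empty-patch SVM on labeled feature sets.

    ``empty_features`` / ``nonempty_features`` are sequences of
    :class:`FeatureVector` (or 2-D arrays). In two-class mode, empty is the
    positive class. Raises if either class is empty (two-class mode) or the
    feature lengths disagree.
    """
    params = params or SVMParams()
    x_non = _stack(nonempty_features) if len(nonempty_features) else None
    x_emp = _stack(empty_features) if len(empty_features) else None

    if params.mode == "one_class":
        if x_non is None:
            raise ValueError("one-class mode needs non-empty (inlier) features")
        dim = x_non.shape[1]
        svm = make_pipeline(
            StandardScaler(),
            OneClassSVM(kernel=params.kernel, gamma=params.gamma, nu=params.nu))
        svm.fit(x_non)
        return EmptyDetector(svm=svm, feature_dim=dim, params=params,
                             n_empty_train=0, n_nonempty_train=x_non.shape[0])

    if x_emp is None or x_non is None:
        raise ValueError("both empty and non-empty feature sets must be non-empty")
    if x_emp.shape[1] != x_non.shape[1]:
        raise ValueError("feature length mismatch between classes")
    x = np.vstack([x_emp, x_non])
    y = np.concatenate([np.ones(x_emp.shape[0], dtype=int),
                        np.zeros(x_non.shape[0], dtype=int)])
    # features are standardized first; class weights balance unequal
    # labeled-set sizes so the minority class is not swallowed
    svm = make_pipeline(
        StandardScaler(),
        SVC(kernel=params.kernel, C=params.C, gamma=params.gamma,
            class_weight="balanced"))
    svm.fit(x, y)
    return EmptyDetector(svm=svm, feature_dim=x.shape[1], params=params,
                         n_empty_train=x_emp.shape[0],
                         n_nonempty_train=x_non.shape[0])


def f1_score(predicted: Sequence[bool], truth: Sequence[bool]) -> float:
    """f1 of the "empty" (positive) class: harmonic mean of precision/recall.

    Defined as 0 (with a warning) when there are neither positive
    predictions nor positive truths.
    """
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have equal length")
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    if tp == 0 and fp == 0 and fn == 0:
        warnings.warn("no positive predictions or truths; f1 defined as 0")
        return 0.0
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def filter_patches(patches: Sequence[PatchPair], detector: EmptyDetector,
                   backbone) -> tuple[list[PatchPair], list[PatchPair]]:
    """Partition patches into (kept, discarded) by the empty detector.

    Order is stable; every input patch lands in exactly one of the lists.
    """
    if not patches:
        return [], []
    feats = np.vstack([
        extract_features(p.bright_field_8bit, backbone, p.patch_id).values
        for p in patches
    ])
    is_empty = detector.predict_empty(feats)
    kept = [p for p, e in zip(patches, is_empty) if not e]
    discarded = [p for p, e in zip(patches, is_empty) if e]
    return kept, discarded
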