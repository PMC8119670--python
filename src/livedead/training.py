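"""Fine-tuning of a convolutional backbone for binary live/dead classification.

Training follows the study design for patch classifiers on weakly labeled
bright-field images: cross-entropy loss, Adam (betas 0.5/0.999, weight decay
1e-5), a weighted random sampler with replacement whose per-class weights
are the inverse class counts (so both classes are drawn equally often
despite severe imbalance), and dihedral data augmentation (random 90-degree
rotations plus horizontal/vertical flips). Model selection keeps the weights
of the epoch with the best validation balanced accuracy.

The class order is fixed as (live, dead); the classifier "score" used
throughout the package is the softmax probability of the live class.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .splits import ClassWeights

__all__ = ["TrainConfig", "TrainedClassifier", "augment", "train", "predict",
           "CLASS_ORDER"]

CLASS_ORDER = ("live", "dead")
PATCH_SIZE = 224


@dataclass(frozen=True)
class TrainConfig:
    backbone: str = "tiny_test"
    learning_rate: float = 1e-5
    batch_size: int = 4
    epochs: int = 30
    adam_betas: tuple[float, float] = (0.5, 0.999)
    weight_decay: float = 1e-5
    augmentation: bool = True
    pretrained: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not all(0.0 < b < 1.0 for b in self.adam_betas):
            raise ValueError("adam betas must lie in (0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


@dataclass
class TrainedClassifier:
    """A trained (or freshly initialized) patch classifier.

    ``input_mean``/``input_scale`` record the fixed intensity normalization
    applied before the network ((x - mean) / scale); training sets them to
    center [0, 1] images at zero with unit-ish spread.
    """

    net: nn.Sequential
    config: TrainConfig
    class_order: tuple[str, str] = CLASS_ORDER
    history: pd.DataFrame = field(default_factory=pd.DataFrame)
    input_size: int = PATCH_SIZE
    input_mean: float = 0.0
    input_scale: float = 1.0


def normalized_batch(model: TrainedClassifier, x: np.ndarray) -> np.ndarray:
    arr = _as_batch(x, model.input_size)
    return (arr - model.input_mean) / model.input_scale


def augment(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply one of the 8 dihedral transforms (rotations by multiples of 90
    degrees, optionally composed with a flip), chosen uniformly at random."""
    if patch.shape[-1] != patch.shape[-2]:
        raise ValueError(f"augmentation requires square patches, got {patch.shape}")
    k = int(rng.integers(0, 4))
    flip = bool(rng.integers(0, 2))
    out = np.rot90(patch, k=k, axes=(-2, -1))
    if flip:
        out = np.flip(out, axis=-1)
    return out.copy()


def _as_batch(x: np.ndarray, input_size: int) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    elif arr.ndim != 4:
        raise ValueError(f"expected 2-D patch or batch, got shape {arr.shape}")
    if arr.shape[-2:] != (input_size, input_size):
        raise ValueError(
            f"patch size {arr.shape[-2:]} does not match model input "
            f"{(input_size, input_size)}"
        )
    return arr


def predict(model: TrainedClassifier, patch: np.ndarray,
            batch_size: int = 64) -> np.ndarray:
    """Softmax class probabilities, ordered (live, dead).

    Accepts a single 2-D patch or a batch; returns (2,) or (N, 2). Hard
    labels are the argmax (``model.class_order[argmax]``).
    """
    single = np.asarray(patch).ndim == 2
    x = normalized_batch(model, patch)
    probs = []
    for i in range(0, x.shape[0], batch_size):
        logits = model.net.forward(x[i:i + batch_size])
        probs.append(nn.softmax(logits))
    out = np.vstack(probs)
    return out[0] if single else out


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    recalls = [
        (y_pred[y_true == c] == c).mean() for c in np.unique(y_true)
    ]
    return float(np.mean(recalls))


def train(config: TrainConfig, train_set, valid_set,
          weights: ClassWeights | None = None) -> TrainedClassifier:
    """Train a backbone on ``train_set`` = (X, y) and select on ``valid_set``.

    ``X`` is (N, H, W) or (N, 1, H, W) float in [0, 1]; ``y`` holds integer
    class indices into ``CLASS_ORDER`` (0=live, 1=dead). An epoch draws
    ``len(X)`` samples with replacement using the class weights. History
    records per-epoch mean training loss and validation balanced accuracy;
    the best-validation weights are restored at the end.
    """
    x_train, y_train = train_set
    x_valid, y_valid = valid_set
    y_train = np.asarray(y_train, dtype=int)
    y_valid = np.asarray(y_valid, dtype=int)
    if len(y_train) == 0 or len(y_valid) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")

    input_size = np.asarray(x_train).shape[-1]
    rng = np.random.default_rng(config.seed)
    net = nn.build_backbone(config.backbone, seed=config.seed)
    model = TrainedClassifier(net=net, config=config, input_size=input_size,
                              input_mean=0.5, input_scale=0.25)

    x_train = normalized_batch(model, x_train)
    x_valid = _as_batch(x_valid, input_size)

    if weights is not None:
        label_names = np.array([CLASS_ORDER[c] for c in y_train])
        p_draw = weights.probabilities(label_names)
    else:
        p_draw = None

    opt = nn.Adam(net, lr=config.learning_rate, betas=config.adam_betas,
                  weight_decay=config.weight_decay)

    n = x_train.shape[0]
    best_ba = -np.inf
    best_weights = net.get_weights()
    rows = []
    for epoch in range(config.epochs):
        idx = rng.choice(n, size=n, replace=True, p=p_draw)
        losses = []
        for start in range(0, n, config.batch_size):
            batch_idx = idx[start:start + config.batch_size]
            xb = x_train[batch_idx]
            if config.augmentation:
                xb = np.stack([augment(im, rng) for im in xb])
            logits = net.forward(xb)
            loss, dlogits = nn.softmax_cross_entropy(logits, y_train[batch_idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_probs = predict(model, x_valid)
        val_pred = val_probs.argmax(axis=1)
        ba = _balanced_accuracy(y_valid, val_pred)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "valid_balanced_accuracy": ba})
        if ba > best_ba:
            best_ba = ba
            best_weights = net.get_weights()

    net.set_weights(best_weights)
    model.history = pd.DataFrame(rows)
    return model


def hard_labels(model: TrainedClassifier, probs: np.ndarray) -> np.ndarray:
    """Map probability rows to class-name labels."""
    idx = np.atleast_2d(probs).argmax(axis=1)
    return np.array([model.class_order[i] for i in idx])
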