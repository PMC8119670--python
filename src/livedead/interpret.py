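"""Model inspection: penultimate-feature embeddings and class activation maps.

Two complementary views into what a trained patch classifier has learned:

* the activation pattern of the layer just before classification (the
  globally pooled last-convolutional features) embedded into 2-D with
  t-SNE, where live and dead patches should form separable clusters and
  boundary patches often contain mixed populations;
* gradient-weighted class activation maps (Grad-CAM): the gradients of a
  target class logit are averaged over space to weight the last
  convolutional layer's activation channels, and the rectified weighted sum
  localizes the image regions driving that class's score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize
from sklearn.manifold import TSNE

from . import nn
from .training import TrainedClassifier, normalized_batch

__all__ = ["EmbeddingMatrix", "ActivationMap", "embed_features", "project_2d",
           "grad_cam"]


@dataclass
class EmbeddingMatrix:
    patch_ids: list[str]
    features: np.ndarray  # (n_patches, n_features)
    truth: np.ndarray | None = None
    predicted: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.features)):
            raise ValueError("embedding features must be finite")
        if len(self.patch_ids) != self.features.shape[0]:
            raise ValueError("one feature row per patch id required")


@dataclass
class ActivationMap:
    patch_id: str
    target_class: int
    heatmap: np.ndarray  # (H, W) in [0, 1], upsampled to the patch size
    predicted_probability: float
    raw_map: np.ndarray | None = None  # pre-normalization map at conv resolution


def _forward_with_conv_cache(net: nn.Sequential, x: np.ndarray):
    """Forward pass returning (logits, last-conv activations, tail layers)."""
    split = net.last_conv_index() + 1
    a = x
    for layer in net.layers[:split]:
        a = layer.forward(a)
    conv_out = a
    for layer in net.layers[split:]:
        a = layer.forward(a)
    return a, conv_out, net.layers[split:]


def embed_features(model: TrainedClassifier, patches: np.ndarray,
                   patch_ids: list[str] | None = None,
                   truth=None, batch_size: int = 64) -> EmbeddingMatrix:
    """Pooled last-convolutional activations (the penultimate layer) per patch."""
    x = normalized_batch(model, patches)
    feats = []
    preds = []
    for i in range(0, x.shape[0], batch_size):
        logits, conv_out, tail = _forward_with_conv_cache(model.net, x[i:i + batch_size])
        pooled = conv_out.mean(axis=(2, 3))
        feats.append(pooled)
        preds.append(nn.softmax(logits).argmax(axis=1))
    features = np.vstack(feats)
    predicted = np.array([model.class_order[i] for i in np.concatenate(preds)])
    ids = patch_ids or [f"patch_{i}" for i in range(features.shape[0])]
    return EmbeddingMatrix(patch_ids=list(ids), features=features,
                           truth=None if truth is None else np.asarray(truth),
                           predicted=predicted)


def project_2d(features: EmbeddingMatrix | np.ndarray, perplexity: float = 30.0,
               seed: int = 0) -> np.ndarray:
    """t-SNE projection of the embedding into 2-D, seed-deterministic."""
    x = features.features if isinstance(features, EmbeddingMatrix) else np.asarray(features)
    n = x.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for n={n}; need n > 3*perplexity"
        )
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(x)


def grad_cam(model: TrainedClassifier, patch: np.ndarray,
             target_class: int) -> ActivationMap:
    """Gradient-weighted class activation map for one patch.

    Channel weights are the spatial averages of the target-class logit's
    gradients at the last convolutional layer; the map is the ReLU of the
    weighted activation sum, min-max normalized to [0, 1] (identically zero
    maps stay zero) and bilinearly upsampled to the patch size.
    """
    if not 0 <= target_class < len(model.class_order):
        raise ValueError(f"target_class {target_class} out of range")
    x = normalized_batch(model, patch)
    if x.shape[0] != 1:
        raise ValueError("grad_cam takes a single patch")
    logits, conv_out, tail = _forward_with_conv_cache(model.net, x)

    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    grad = dlogits
    for layer in reversed(tail):
        grad = layer.backward(grad)
    dconv = grad  # (1, C, h, w): d logit / d last-conv activations

    alphas = dconv[0].mean(axis=(1, 2))  # (C,)
    cam = np.maximum((alphas[:, None, None] * conv_out[0]).sum(axis=0), 0.0)
    raw = cam.copy()
    heat = resize(cam, (model.input_size, model.input_size), order=1,
                  mode="edge", anti_aliasing=False)
    # min-max normalize after upsampling so the displayed peak is exactly 1;
    # identically zero maps stay zero
    if heat.max() > 0:
        heat = (heat - heat.min()) / (heat.max() - heat.min())
    heat = np.clip(heat, 0.0, 1.0)
    prob = float(nn.softmax(logits)[0, target_class])
    return ActivationMap(patch_id="", target_class=target_class,
                         heatmap=heat, predicted_probability=prob, raw_map=raw)


def save_projection_plot(points: np.ndarray, labels, path,
                         predicted=None) -> None:
    """Scatter of the 2-D projection colored by label; white dots mark
    patches whose predicted and truth labels disagree."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for lab, color in (("live", "tab:green"), ("dead", "tab:red")):
        m = labels == lab
        ax.scatter(points[m, 0], points[m, 1], s=8, c=color, label=lab)
    if predicted is not None:
        wrong = np.asarray(predicted) != labels
        ax.scatter(points[wrong, 0], points[wrong, 1], s=10, c="white",
                   edgecolors="k", linewidths=0.3, label="misclassified")
    ax.legend()
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
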