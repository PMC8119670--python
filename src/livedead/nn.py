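"""Minimal convolutional-network core used by the trainable backbones.

Implements exactly the pieces the patch classifiers need — strided valid
convolution (im2col), ReLU, global average pooling, a linear head, softmax
cross-entropy and Adam — with explicit forward/backward passes on numpy
arrays. Keeping the autodiff surface this small makes gradients into any
intermediate layer directly accessible, which the class-activation-map
machinery relies on.

Layout convention: batches are ``(N, C, H, W)`` float64 arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "GlobalAvgPool", "Linear", "Sequential",
           "Adam", "softmax", "softmax_cross_entropy", "build_backbone",
           "register_backbone"]


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """View ``x`` (N,C,H,W) as (N, Ho, Wo, C*k*k) patch columns."""
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    s = x.strides
    shape = (n, c, ho, wo, k, k)
    strides = (s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3])
    cols = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    # (N, Ho, Wo, C, k, k) -> (N, Ho, Wo, C*k*k)
    return np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, ho, wo, c * k * k)


class Conv2d:
    """Valid (no padding) strided 2-D convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_ch, in_ch, kernel, kernel))
        self.b = np.zeros(out_ch)
        self.kernel = kernel
        self.stride = stride
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols = _im2col(x, self.kernel, self.stride)
        out = cols @ self.w.reshape(self.w.shape[0], -1).T + self.b
        self._cache = (x.shape, cols)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        n, _, ho, wo = grad.shape
        g = grad.transpose(0, 2, 3, 1)  # (N, Ho, Wo, out)
        wmat = self.w.reshape(self.w.shape[0], -1)
        self.dw = (g.reshape(-1, g.shape[-1]).T @ cols.reshape(-1, cols.shape[-1])
                   ).reshape(self.w.shape)
        self.db = g.sum(axis=(0, 1, 2))
        dcols = g @ wmat  # (N, Ho, Wo, C*k*k)
        k, s = self.kernel, self.stride
        _, c, h, w = x_shape
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        dx = np.zeros(x_shape)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + ho * s:s, j:j + wo * s:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dx

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def params(self):
        return []


class GlobalAvgPool:
    """(N, C, H, W) -> (N, C) spatial average."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               self._shape).copy()

    def params(self):
        return []


class Linear:
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(1.0 / in_dim), size=(out_dim, in_dim))
        self.b = np.zeros(out_dim)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = grad.T @ self._x
        self.db = grad.sum(axis=0)
        return grad @ self.w

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    __call__ = forward

    def parameters(self):
        """Flat list of (layer, name, value-array, grad-attr) tuples."""
        out = []
        for layer in self.layers:
            for name, arr, gname in layer.params():
                out.append((layer, name, arr, gname))
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [arr.copy() for _, _, arr, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match model parameters")
        for (layer, name, arr, _), w in zip(params, weights):
            if arr.shape != w.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {w.shape}")
            arr[...] = w

    def last_conv_index(self) -> int:
        idx = [i for i, l in enumerate(self.layers) if isinstance(l, Conv2d)]
        if not idx:
            raise ValueError("model has no convolutional layer")
        return idx[-1]


class Adam:
    """Adam with decoupled-from-nothing plain L2 weight decay added to grads."""

    def __init__(self, model: Sequential, lr: float = 1e-5,
                 betas: tuple[float, float] = (0.5, 0.999),
                 weight_decay: float = 1e-5, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.wd = weight_decay
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(arr) for _, _, arr, _ in model.parameters()]
        self.v = [np.zeros_like(arr) for _, _, arr, _ in model.parameters()]

    def step(self) -> None:
        self.t += 1
        for i, (layer, name, arr, gname) in enumerate(self.model.parameters()):
            g = getattr(layer, gname) + self.wd * arr
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


def _build_tiny(seed: int = 0, in_ch: int = 1, n_classes: int = 2) -> Sequential:
    """Three strided conv blocks + GAP + linear head; < 10k parameters.

    224x224 input -> 55 -> 27 -> 13 feature maps, 32 pooled features.
    Small enough to fine-tune on a laptop CPU in minutes yet expressive
    enough to separate the morphological live/dead cues of synthetic data.
    """
    rng = np.random.default_rng(seed)
    return Sequential([
        Conv2d(in_ch, 8, kernel=5, stride=4, rng=rng), ReLU(),
        Conv2d(8, 16, kernel=3, stride=2, rng=rng), ReLU(),
        Conv2d(16, 32, kernel=3, stride=2, rng=rng), ReLU(),
        GlobalAvgPool(),
        Linear(32, n_classes, rng=rng),
    ])


def _unavailable(name: str):
    def _raise(*_args, **_kwargs):
        raise NotImplementedError(
            f"backbone {name!r} is a pluggable interface for pretrained "
            "networks; register an implementation with register_backbone() "
            "or use 'tiny_test'"
        )
    return _raise


_BACKBONES = {
    "tiny_test": _build_tiny,
    "residual18": _unavailable("residual18"),
    "squeeze": _unavailable("squeeze"),
    "inception_v3": _unavailable("inception_v3"),
}


def register_backbone(name: str, builder) -> None:
    """Register ``builder(seed, in_ch, n_classes) -> Sequential-like``."""
    _BACKBONES[name] = builder


def build_backbone(name: str, seed: int = 0, in_ch: int = 1,
                   n_classes: int = 2) -> Sequential:
    if name not in _BACKBONES:
        raise KeyError(f"unknown backbone {name!r}; known: {sorted(_BACKBONES)}")
    return _BACKBONES[name](seed=seed, in_ch=in_ch, n_classes=n_classes)
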