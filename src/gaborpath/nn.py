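"""Minimal NumPy feedforward network engine.

Implements the small set of layer types needed for the contour-integration
experiments (conv, relu, max/avg pooling, linear, dropout) with explicit
forward and backward passes, He-style initialization, SGD-with-momentum and
AdamW optimizers, a one-cycle learning-rate schedule, and softmax
cross-entropy. The backward pass supports a *guided* mode in which each
rectifier additionally zeroes negative incoming gradients, which is the
attribution rule used for saliency maps.

Everything is deterministic given the seeds passed in; there is no hidden
global state.
"""

from __future__ import annotations

import hashlib
import math
from typing import Iterable

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "AvgPool2d",
    "AdaptiveAvgPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Dropout",
    "Sequential",
    "SGD",
    "AdamW",
    "one_cycle_lr",
    "softmax",
    "cross_entropy",
    "parameter_hash",
]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base class: stateless unless it owns parameters.

    ``forward`` caches whatever ``backward`` needs on ``self``; models are
    single-threaded so this is safe.
    """

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


def _he_init(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape).astype(np.float64)


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _windows(x: np.ndarray, k: int, s: int) -> np.ndarray:
    """(N,C,H,W) -> view (N,C,Ho,Wo,k,k)."""
    v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return v[:, :, ::s, ::s]


class Conv2d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, seed: int = 0):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        rng = np.random.default_rng(seed)
        fan_in = in_channels * kernel * kernel
        self.W = _he_init((out_channels, in_channels, kernel, kernel), fan_in, rng)
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def out_size(self, h: int) -> int:
        return (h + 2 * self.padding - self.kernel) // self.stride + 1

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        k, s = self.kernel, self.stride
        xp = _pad(x, self.padding)
        ho, wo = self.out_size(h), self.out_size(w)
        cols = _windows(xp, k, s).reshape(n, c, ho, wo, k * k)
        # (N, Ho, Wo, C*k*k)
        cols = cols.transpose(0, 2, 3, 1, 4).reshape(n, ho * wo, c * k * k)
        wmat = self.W.reshape(self.out_channels, c * k * k)
        out = cols @ wmat.T + self.b
        self._cols = cols
        self._xshape = x.shape
        self._hw = (ho, wo)
        return out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, grad, guided=False):
        n, c, h, w = self._xshape
        k, s, p = self.kernel, self.stride, self.padding
        ho, wo = self._hw
        g = grad.transpose(0, 2, 3, 1).reshape(n, ho * wo, self.out_channels)
        wmat = self.W.reshape(self.out_channels, c * k * k)
        self.dW = (g.reshape(-1, self.out_channels).T
                   @ self._cols.reshape(-1, c * k * k)).reshape(self.W.shape)
        self.db = g.sum(axis=(0, 1))
        dcols = (g @ wmat).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class InputCenter(Layer):
    """Subtract a fixed offset (mid-gray for [0,1] rasters); gradient is
    the identity. Keeps datasets in raster units while giving the conv
    stack zero-mean inputs."""

    def __init__(self, offset: float = 0.5):
        self.offset = offset

    def forward(self, x, train=False, rng=None):
        return x - self.offset

    def backward(self, grad, guided=False):
        return grad


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad, guided=False):
        g = grad * self._mask
        if guided:
            g = np.where(g > 0, g, 0.0)
        return g


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int):
        self.kernel = kernel
        self.stride = stride

    def out_size(self, h: int) -> int:
        return (h - self.kernel) // self.stride + 1

    def forward(self, x, train=False, rng=None):
        k, s = self.kernel, self.stride
        v = _windows(x, k, s)
        n, c, ho, wo = v.shape[:4]
        flat = v.reshape(n, c, ho, wo, k * k)
        self._arg = flat.argmax(axis=-1)
        self._xshape = x.shape
        self._hw = (ho, wo)
        return flat.max(axis=-1)

    def backward(self, grad, guided=False):
        n, c, h, w = self._xshape
        k, s = self.kernel, self.stride
        ho, wo = self._hw
        dx = np.zeros((n, c, h, w))
        for i in range(k):
            for j in range(k):
                mask = self._arg == i * k + j
                dx[:, :, i:i + s * ho:s, j:j + s * wo:s] += grad * mask
        return dx


class AvgPool2d(Layer):
    def __init__(self, kernel: int, stride: int):
        self.kernel = kernel
        self.stride = stride

    def out_size(self, h: int) -> int:
        return (h - self.kernel) // self.stride + 1

    def forward(self, x, train=False, rng=None):
        k, s = self.kernel, self.stride
        v = _windows(x, k, s)
        self._xshape = x.shape
        self._hw = v.shape[2], v.shape[3]
        return v.mean(axis=(4, 5))

    def backward(self, grad, guided=False):
        n, c, h, w = self._xshape
        k, s = self.kernel, self.stride
        ho, wo = self._hw
        dx = np.zeros((n, c, h, w))
        g = grad / (k * k)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + s * ho:s, j:j + s * wo:s] += g
        return dx


class AdaptiveAvgPool2d(Layer):
    """Average pool to a fixed output grid using torch-style integer bins."""

    def __init__(self, out: int):
        self.out = out

    @staticmethod
    def _edges(n_in: int, n_out: int) -> list[tuple[int, int]]:
        return [(math.floor(i * n_in / n_out), math.ceil((i + 1) * n_in / n_out))
                for i in range(n_out)]

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        o = self.out
        self._xshape = x.shape
        rows, cols = self._edges(h, o), self._edges(w, o)
        self._bins = (rows, cols)
        out = np.empty((n, c, o, o))
        for i, (r0, r1) in enumerate(rows):
            for j, (c0, c1) in enumerate(cols):
                out[:, :, i, j] = x[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
        return out

    def backward(self, grad, guided=False):
        dx = np.zeros(self._xshape)
        rows, cols = self._bins
        for i, (r0, r1) in enumerate(rows):
            for j, (c0, c1) in enumerate(cols):
                area = (r1 - r0) * (c1 - c0)
                dx[:, :, r0:r1, c0:c1] += grad[:, :, i:i + 1, j:j + 1] / area
        return dx


class GlobalAvgPool(Layer):
    """Spatial mean; output (N, C). Makes the head input-size independent."""

    def forward(self, x, train=False, rng=None):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad, guided=False):
        n, c, h, w = self._xshape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._xshape).copy()


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, guided=False):
        return grad.reshape(self._xshape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W = _he_init((out_features, in_features), in_features, rng)
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad, guided=False):
        self.dW = grad.T @ self._x
        self.db = grad.sum(axis=0)
        return grad @ self.W

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class Dropout(Layer):
    def __init__(self, p: float = 0.5):
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in train mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad, guided=False):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential:
    """Ordered, named layer stack with forward-to-a-probe-point support."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.names = [n for n, _ in layers]
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate layer names")
        self.layers = [l for _, l in layers]

    def __getitem__(self, name: str) -> Layer:
        return self.layers[self.names.index(name)]

    def forward(self, x: np.ndarray, upto: str | None = None, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if upto is not None and upto not in self.names:
            raise KeyError(f"unknown layer {upto!r}")
        self._ran: list[Layer] = []
        for name, layer in zip(self.names, self.layers):
            x = layer.forward(x, train=train, rng=rng)
            self._ran.append(layer)
            if name == upto:
                break
        return x

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        for layer in reversed(self._ran):
            grad = layer.backward(grad, guided=guided)
        return grad

    def parameters(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.gradients()]


# ---------------------------------------------------------------------------
# loss / optimizers
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return float(loss), g / n


def one_cycle_lr(step: int, total_steps: int, max_lr: float,
                 pct_start: float = 0.4, div: float = 25.0,
                 final_div: float = 1e4) -> float:
    """One-cycle schedule: linear warm-up for ``pct_start`` of the steps,
    cosine anneal down afterwards."""
    if total_steps <= 1:
        return max_lr
    up = max(1, int(round(pct_start * total_steps)))
    lo0 = max_lr / div
    if step < up:
        return lo0 + (max_lr - lo0) * step / up
    t = (step - up) / max(1, total_steps - up)
    lo1 = max_lr / final_div
    return lo1 + (max_lr - lo1) * 0.5 * (1.0 + math.cos(math.pi * t))


class SGD:
    def __init__(self, params: Iterable[np.ndarray], momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.vel = [np.zeros_like(p) for p in self.params]

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        for p, g, v in zip(self.params, grads, self.vel):
            if self.weight_decay:
                g = g + self.weight_decay * p
            v *= self.momentum
            v += g
            p -= lr * v


class AdamW:
    def __init__(self, params: Iterable[np.ndarray], betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p -= lr * (mh / (np.sqrt(vh) + self.eps) + self.weight_decay * p)


def parameter_hash(model: Sequential) -> str:
    """SHA-256 over all parameter bytes; used to assert frozen backbones."""
    h = hashlib.sha256()
    for p in model.parameters():
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()
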