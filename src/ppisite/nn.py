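"""Minimal NumPy neural-network core: the layers the classifier is built from.

Implements exactly what the architecture needs — 1-D valid convolution with
stride 1, ReLU, per-sample layer normalization, inverted dropout, dense
layers, a sigmoid output, binary cross-entropy and SGD with momentum — with
explicit forward/backward passes. Arrays flow as float32 by default
(float64 for gradient checking).

Conventions: convolution inputs are (B, L, C) with features as channels;
``backward`` consumes the gradient of the loss w.r.t. a layer's output and
returns it w.r.t. the input, accumulating parameter gradients on the layer.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = [
    "relu",
    "sigmoid",
    "bce_loss",
    "bce_grad",
    "Layer",
    "Conv1D",
    "ReLU",
    "LayerNorm",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "SGD",
    "EPS_CLIP",
]

#: Scores are clipped this far inside (0, 1) before taking logs.
EPS_CLIP = 1e-7


def relu(f: np.ndarray | float) -> np.ndarray | float:
    """max(0, f)."""
    return np.maximum(0.0, f)


def sigmoid(f: np.ndarray | float) -> np.ndarray | float:
    """1 / (1 + exp(-f)), computed stably for large |f|."""
    f = np.asarray(f, dtype=float)
    out = np.empty_like(f)
    pos = f >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-f[pos]))
    ef = np.exp(f[~pos])
    out[~pos] = ef / (1.0 + ef)
    if out.ndim == 0:
        return float(out)
    return out


def bce_loss(labels: np.ndarray, scores: np.ndarray,
             pos_weight: float = 1.0) -> float:
    """Mean binary cross-entropy -(1/n) sum a_i log b_i + (1-a_i) log(1-b_i).

    Scores exactly at 0 or 1 are clipped to ``EPS_CLIP`` inside the interval
    so the loss is always finite. ``pos_weight`` optionally scales the
    positive-class term (1.0 = the plain loss).
    """
    a = np.asarray(labels, dtype=float).ravel()
    b = np.asarray(scores, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("labels and scores must have equal length")
    if a.size == 0:
        raise ValueError("empty input")
    b = np.clip(b, EPS_CLIP, 1.0 - EPS_CLIP)
    terms = pos_weight * a * np.log(b) + (1.0 - a) * np.log(1.0 - b)
    return float(-np.mean(terms))


def bce_grad(labels: np.ndarray, scores: np.ndarray,
             pos_weight: float = 1.0) -> np.ndarray:
    """Gradient of mean BCE w.r.t. the pre-sigmoid logit (stable, exact).

    For the plain loss this is (b - a) / n.
    """
    a = np.asarray(labels, dtype=float).ravel()
    b = np.asarray(scores, dtype=float).ravel()
    n = a.size
    return (b * (pos_weight * a + 1.0 - a) - pos_weight * a) / n


class Layer:
    """Base layer: parameters and their gradients live in parallel lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid 1-D convolution, stride 1, along the window axis.

    Weight shape (k, C_in, C_out); output length L - k + 1. Implemented as k
    shifted matrix products, which keeps both passes in BLAS.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.k = kernel
        fan_in = kernel * in_channels
        scale = math.sqrt(2.0 / fan_in)  # He init, ReLU follows every conv
        self.W = rng.normal(0.0, scale, size=(kernel, in_channels, out_channels)).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, L, C = x.shape
        if L < self.k:
            raise ValueError(f"input length {L} < kernel {self.k}")
        Lout = L - self.k + 1
        y = np.zeros((B, Lout, self.W.shape[2]), dtype=x.dtype)
        for j in range(self.k):
            y += x[:, j : j + Lout, :] @ self.W[j]
        y += self.b
        if train:
            self._x = x
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._x
        B, L, C = x.shape
        Lout = grad_out.shape[1]
        dx = np.zeros_like(x)
        for j in range(self.k):
            xj = x[:, j : j + Lout, :].reshape(B * Lout, C)
            gj = grad_out.reshape(B * Lout, -1)
            self.grads[0][j] += xj.T @ gj
            dx[:, j : j + Lout, :] += grad_out @ self.W[j].T
        self.grads[1] += grad_out.sum(axis=(0, 1))
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(0.0, x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class LayerNorm(Layer):
    """Normalize each sample over all remaining axes (position, channel)."""

    def __init__(self, shape: tuple[int, ...], eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.eps = eps
        self.gamma = np.ones(shape, dtype=dtype)
        self.beta = np.zeros(shape, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self._axes = tuple(range(1, 1 + len(shape)))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mu = x.mean(axis=self._axes, keepdims=True)
        var = x.var(axis=self._axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._xhat, self._inv = xhat, inv
        return self.gamma * xhat + self.beta

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        axes = self._axes
        self.grads[0] += (grad_out * xhat).sum(axis=0)
        self.grads[1] += grad_out.sum(axis=0)
        g = grad_out * self.gamma
        m1 = g.mean(axis=axes, keepdims=True)
        m2 = (g * xhat).mean(axis=axes, keepdims=True)
        return inv * (g - m1 - xhat * m2)


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self.p == 0.0:
            return grad_out
        return grad_out * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        scale = math.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, scale, size=(in_features, out_features)).astype(dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ grad_out
        self.grads[1] += grad_out.sum(axis=0)
        return grad_out @ self.W.T


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)
        self.params = [p for l in self.layers for p in l.params]
        self.grads = [g for l in self.layers for g in l.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray],
                 lr: float = 0.01, momentum: float = 0.9) -> None:
        self.params = list(params)
        self.grads = list(grads)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in self.params]

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def step(self) -> None:
        for p, g, v in zip(self.params, self.grads, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v
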