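"""Minimal 1D convolutional network layers with hand-derived backprop.

Everything operates on float32 arrays shaped ``(N, C, L)`` — batch, channel,
axial position.  Each layer caches what its backward pass needs on the
instance, so a model is used single-threaded: ``forward`` then ``backward``
in matching order.  The only optimizer provided is Adam, which is all the
training recipe calls for.

Conv1d uses zero "same" padding (odd kernels only), so every layer preserves
length exactly and pooling divides it exactly; without same padding the
length bookkeeping of a U-net with single convolutions per block would not
close.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "ConvTranspose1d",
    "softmax",
    "Adam",
]

_F32 = np.float32


class Layer:
    def params(self) -> list[dict]:
        return []


class Conv1d(Layer):
    """Same-padded 1D convolution (cross-correlation), odd kernel."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        std = np.sqrt(2.0 / (c_in * k))
        self.W = rng.normal(0.0, std, size=(c_out, c_in * k)).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, L = x.shape
        p = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        # (N, C, L, k) windows -> (N*L, C*k)
        cols = sliding_window_view(xp, self.k, axis=2)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(n * L, c * self.k)
        y = cols @ self.W.T + self.b
        if train:
            self._cols, self._shape = cols, (n, c, L)
        return y.reshape(n, L, self.c_out).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, L = self._shape
        p = (self.k - 1) // 2
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(n * L, self.c_out)
        self.dW[...] = dyf.T @ self._cols
        self.db[...] = dyf.sum(axis=0)
        dcols = (dyf @ self.W).reshape(n, L, c, self.k).transpose(0, 2, 1, 3)
        dxp = np.zeros((n, c, L + 2 * p), dtype=_F32)
        for j in range(self.k):
            dxp[:, :, j : j + L] += dcols[:, :, :, j]
        self._cols = None
        return dxp[:, :, p : p + L]

    def params(self) -> list[dict]:
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over batch and position."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=_F32)
        self.beta = np.zeros(c, dtype=_F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(_F32)
        xhat = (x - mean[:, None]) / std[:, None]
        if train:
            self._xhat, self._std = xhat, std
        return (self.gamma[:, None] * xhat + self.beta[:, None]).astype(_F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        m = dy.shape[0] * dy.shape[2]
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2))
        self.dbeta[...] = dy.sum(axis=(0, 2))
        g = self.gamma[:, None] / std[:, None]
        dx = g * (
            dy
            - dy.mean(axis=(0, 2), keepdims=True)
            - xhat * (dy * xhat).sum(axis=(0, 2), keepdims=True) / m
        )
        self._xhat = None
        return dx.astype(_F32)

    def params(self) -> list[dict]:
        return [
            {"value": self.gamma, "grad": self.dgamma},
            {"value": self.beta, "grad": self.dbeta},
        ]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._pos = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._pos
        self._pos = None
        return dx


class MaxPool1d(Layer):
    """Non-overlapping max pooling, kernel == stride == s; L must divide by s."""

    def __init__(self, s: int):
        self.s = s

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, L = x.shape
        if L % self.s:
            raise ValueError(f"length {L} not divisible by pool size {self.s}")
        xr = x.reshape(n, c, L // self.s, self.s)
        idx = xr.argmax(axis=3)
        if train:
            self._idx, self._shape = idx, (n, c, L)
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, L = self._shape
        dxr = np.zeros((n, c, L // self.s, self.s), dtype=_F32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=3)
        self._idx = None
        return dxr.reshape(n, c, L)


class ConvTranspose1d(Layer):
    """Transposed convolution with kernel == stride == s (pure upsampling,
    no output overlap)."""

    def __init__(self, c_in: int, c_out: int, s: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.s = c_in, c_out, s
        std = np.sqrt(2.0 / c_in)
        self.W = rng.normal(0.0, std, size=(c_in, c_out, s)).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, L = x.shape
        if train:
            self._x = x
        y = np.einsum("ncl,cdj->ndlj", x, self.W, optimize=True)
        y = y.reshape(n, self.c_out, L * self.s) + self.b[:, None]
        return y.astype(_F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0]
        L = dy.shape[2] // self.s
        dy4 = dy.reshape(n, self.c_out, L, self.s)
        self.dW[...] = np.einsum("ncl,ndlj->cdj", self._x, dy4, optimize=True)
        self.db[...] = dy.sum(axis=(0, 2))
        dx = np.einsum("ndlj,cdj->ncl", dy4, self.W, optimize=True)
        self._x = None
        return dx.astype(_F32)

    def params(self) -> list[dict]:
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam with the usual bias-corrected moment estimates."""

    def __init__(self, params: list[dict], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p["value"] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
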