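"""Layers with explicit forward/backward passes, plus Adam.

Tensors are ``float32`` with layout ``(batch, channels, length)`` for
convolutional stages and ``(batch, features)`` for dense stages.  Each layer
caches what its backward pass needs during ``forward``; ``backward`` returns
the gradient with respect to the layer input and accumulates parameter
gradients in place.  Convolutions use 'same' zero padding via an
im2col/matmul formulation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A named trainable array with its gradient buffer."""

    __slots__ = ("name", "value", "grad", "trainable")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    @property
    def size(self) -> int:
        return self.value.size


class Conv1d:
    """1-D convolution with 'same' zero padding and optional stride.

    Weight shape ``(out_ch, in_ch, kernel)``; He fan-in initialization.
    Output length is ``ceil(L / stride)``.
    """

    def __init__(self, name: str, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_ch * kernel))
        self.w = Parameter(f"{name}.weight",
                           rng.normal(0.0, std, (out_ch, in_ch, kernel)).astype(np.float32))
        self.b = Parameter(f"{name}.bias", np.zeros(out_ch, dtype=np.float32))
        self.kernel, self.stride = kernel, stride
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache: tuple | None = None

    @property
    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        B, C, L = x.shape
        k, s = self.kernel, self.stride
        L_out = -(-L // s)
        pad_total = max((L_out - 1) * s + k - L, 0)
        pl = pad_total // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pad_total - pl)))
        cols = sliding_window_view(xp, k, axis=2)[:, :, ::s, :]  # (B, C, L_out, k)
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B, L_out, C * k)
        w2 = self.w.value.reshape(self.out_ch, C * k)
        out = cols2 @ w2.T + self.b.value
        if cache:
            self._cache = (cols2, (B, C, L), xp.shape[2], pl, L_out)
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols2, (B, C, L), Lp, pl, L_out = self._cache
        k, s = self.kernel, self.stride
        g = np.ascontiguousarray(gout.transpose(0, 2, 1))  # (B, L_out, out_ch)
        gw2 = g.reshape(-1, self.out_ch).T @ cols2.reshape(-1, C * k)
        self.w.grad += gw2.reshape(self.w.value.shape)
        self.b.grad += g.sum(axis=(0, 1))
        gcols = (g @ self.w.value.reshape(self.out_ch, C * k)).reshape(B, L_out, C, k)
        gcols = gcols.transpose(0, 2, 1, 3)  # (B, C, L_out, k)
        gxp = np.zeros((B, C, Lp), dtype=np.float32)
        for j in range(k):
            gxp[:, :, j:j + s * (L_out - 1) + 1:s] += gcols[:, :, :, j]
        return gxp[:, :, pl:pl + L]


class Linear:
    def __init__(self, name: str, in_f: int, out_f: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_f)
        self.w = Parameter(f"{name}.weight", rng.normal(0.0, std, (out_f, in_f)).astype(np.float32))
        self.b = Parameter(f"{name}.bias", np.zeros(out_f, dtype=np.float32))
        self._x: np.ndarray | None = None

    @property
    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        if cache:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.w.grad += gout.T @ self._x
        self.b.grad += gout.sum(axis=0)
        return gout @ self.w.value


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if cache:
            self._mask = x > 0
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class AvgPool1d:
    """Non-overlapping average pooling; a trailing remainder shorter than
    the window is dropped (and receives zero gradient)."""

    def __init__(self, width: int):
        self.width = width
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        B, C, L = x.shape
        w = self.width
        L_out = L // w
        if cache:
            self._shape = (B, C, L, L_out)
        return x[:, :, :L_out * w].reshape(B, C, L_out, w).mean(axis=3)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        B, C, L, L_out = self._shape
        gx = np.zeros((B, C, L), dtype=np.float32)
        gx[:, :, :L_out * self.width] = np.repeat(gout / self.width, self.width, axis=2)
        return gx


class GlobalAvgPool:
    def __init__(self):
        self._L: int | None = None

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        if cache:
            self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.repeat(gout[:, :, None], self._L, axis=2) / self._L


class Dropout:
    """Inverted dropout; identity when not training or when p == 0."""

    def __init__(self, p: float):
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None,
                cache: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            if cache:
                self._mask = None
            return x
        keep = 1.0 - self.p
        mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        if cache:
            self._mask = mask
        return x * mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout if self._mask is None else gout * self._mask


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    logits = logits.ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    z = logits.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / len(y)
    return loss, grad.astype(np.float32)


class Adam:
    """Adam with per-parameter state; frozen parameters are skipped."""

    def __init__(self, params: list[Parameter], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {id(p): np.zeros_like(p.value) for p in params}
        self._v = {id(p): np.zeros_like(p.value) for p in params}

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in self.params:
            if not p.trainable:
                continue
            m, v = self._m[id(p)], self._v[id(p)]
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
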