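"""Minimal NumPy neural-network layers with explicit backpropagation.

Just enough machinery for the fusion surrogate: same-padded 2-D
convolution (im2col), 2x2 max pooling, dense layers, an LSTM with full
backpropagation through time, scaled-dot attention pooling, and Adam.
Everything runs in float32 on the CPU.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv2D:
    """Same-padded square convolution, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(_he_init(rng, (kernel * kernel * c_in, c_out), kernel * kernel * c_in))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        n, h, w, c = x.shape
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((n, h, w, k * k * c), dtype=DTYPE)
        idx = 0
        for di in range(k):
            for dj in range(k):
                cols[..., idx * c : (idx + 1) * c] = x[:, di : di + h, dj : dj + w, :]
                idx += 1
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = self._im2col(x)
        flat = cols.reshape(-1, cols.shape[-1])
        out = flat @ self.W.value + self.b.value
        self._cache = (flat, x.shape)
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray, need_dx: bool = True) -> Optional[np.ndarray]:
        flat, x_shape = self._cache
        n, h, w, c = x_shape
        k = self.kernel
        p = k // 2
        dflat = dout.reshape(-1, self.c_out)
        self.W.grad += flat.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        if not need_dx:
            return None
        dcols = (dflat @ self.W.value.T).reshape(n, h, w, k * k * c)
        dx_pad = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=DTYPE)
        idx = 0
        for di in range(k):
            for dj in range(k):
                dx_pad[:, di : di + h, dj : dj + w, :] += dcols[..., idx * c : (idx + 1) * c]
                idx += 1
        return dx_pad[:, p : p + h, p : p + w, :] if p else dx_pad


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2:
    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._cache = (xr, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xr, out = self._cache
        mask = xr == out[:, :, None, :, None, :]
        # split ties evenly so gradients stay exact
        counts = mask.sum(axis=(2, 4), keepdims=True)
        d = mask * (dout[:, :, None, :, None, :] / counts)
        n, hh, _, ww, _, c = xr.shape
        return d.reshape(n, hh * 2, ww * 2, c)


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(_he_init(rng, (d_in, d_out), d_in))
        self.b = Param(np.zeros(d_out, dtype=DTYPE))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class LSTM:
    """Single-layer LSTM returning the full hidden sequence (N, T, H)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.d_in, self.hidden = d_in, hidden
        scale = 1.0 / math.sqrt(hidden)
        self.Wx = Param((rng.standard_normal((d_in, 4 * hidden)) * scale).astype(DTYPE))
        self.Wh = Param((rng.standard_normal((hidden, 4 * hidden)) * scale).astype(DTYPE))
        self.b = Param(np.zeros(4 * hidden, dtype=DTYPE))
        # forget-gate bias at 1 for stable early training
        self.b.value[hidden : 2 * hidden] = 1.0
        self._cache = None

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, T, _ = x.shape
        H = self.hidden
        h = np.zeros((n, H), dtype=DTYPE)
        c = np.zeros((n, H), dtype=DTYPE)
        hs = np.zeros((n, T, H), dtype=DTYPE)
        caches = []
        for t in range(T):
            gates = x[:, t, :] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(gates[:, :H])
            f = _sigmoid(gates[:, H : 2 * H])
            g = np.tanh(gates[:, 2 * H : 3 * H])
            o = _sigmoid(gates[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            caches.append((x[:, t, :], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._cache = (caches, x.shape)
        return hs

    def backward(self, dhs: np.ndarray, need_dx: bool = True) -> Optional[np.ndarray]:
        caches, x_shape = self._cache
        n, T, _ = x_shape
        H = self.hidden
        dx = np.zeros(x_shape, dtype=DTYPE) if need_dx else None
        dh_next = np.zeros((n, H), dtype=DTYPE)
        dc_next = np.zeros((n, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = caches[t]
            dh = dhs[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dgates = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.Wx.grad += x_t.T @ dgates
            self.Wh.grad += h_prev.T @ dgates
            self.b.grad += dgates.sum(axis=0)
            if need_dx:
                dx[:, t, :] = dgates @ self.Wx.value.T
            dh_next = dgates @ self.Wh.value.T
            dc_next = dc * f
        return dx


def attention_weights(scores: np.ndarray, d_k: int) -> np.ndarray:
    """softmax(scores / sqrt(d_k)) along the last axis."""
    s = np.asarray(scores, dtype=float) / math.sqrt(d_k)
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def attention_pool(features: np.ndarray, scores: np.ndarray, d_k: int = 1) -> np.ndarray:
    """Weighted sum of feature vectors with softmax(scores/sqrt(d_k)).

    ``features``: (T, D) or (N, T, D); ``scores``: matching (T,) or (N, T).
    """
    F = np.asarray(features, dtype=float)
    if F.size == 0:
        raise ValueError("empty feature list")
    alpha = attention_weights(scores, d_k)
    return np.einsum("...t,...td->...d", alpha, F)


class AttentionPoolLayer:
    """Learned scaled-dot attention pooling over a hidden sequence."""

    def __init__(self, d_model: int, d_k: Optional[int] = None, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.d_k = d_k or d_model
        self.v = Param((rng.standard_normal(d_model) / math.sqrt(d_model)).astype(DTYPE))
        self._cache = None

    def params(self):
        return [self.v]

    def forward(self, H: np.ndarray) -> np.ndarray:
        scores = H @ self.v.value  # (N, T)
        alpha = attention_weights(scores, self.d_k).astype(DTYPE)
        out = np.einsum("nt,ntd->nd", alpha, H).astype(DTYPE)
        self._cache = (H, alpha)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H, alpha = self._cache
        dH = alpha[:, :, None] * dout[:, None, :]
        da = np.einsum("nd,ntd->nt", dout, H)
        ds = alpha * (da - (alpha * da).sum(axis=1, keepdims=True))
        ds = ds / math.sqrt(self.d_k)
        dH += ds[:, :, None] * self.v.value[None, None, :]
        self.v.grad += np.einsum("nt,ntd->d", ds, H)
        return dH.astype(DTYPE)


class Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + 2.0 * self.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def clip_gradients(params, max_norm: float) -> float:
    """Global-norm gradient clipping; returns the pre-clip norm."""
    total = math.sqrt(sum(float((p.grad**2).sum()) for p in params))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total
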