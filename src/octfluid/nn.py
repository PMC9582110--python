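"""Minimal CPU neural-network layers for the slice-wise segmentation U-net.

Implements exactly the operators the U-net needs — 2D convolution (im2col +
BLAS GEMM), batch normalisation, ReLU, 2x2 max pooling, 2x2-stride-2
transposed convolution, sigmoid — each with an explicit backward pass, plus
stochastic gradient descent with Nesterov momentum.  All tensors are
``float32`` in ``(N, C, H, W)`` layout.

Layers cache what their backward pass needs during a ``training=True``
forward call; caches are released after ``backward``.  Gradients are exposed
per-layer in ``.grads`` keyed like ``.params``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_F32 = np.float32


def _conv2d_gemm(x: np.ndarray, weight: np.ndarray, padding: int) -> np.ndarray:
    """Stride-1 cross-correlation of (N,C,H,W) with (F,C,k,k) via one GEMM."""
    n, c, h, w = x.shape
    f, _, k, _ = weight.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = sliding_window_view(x, (k, k), axis=(2, 3))  # N,C,H',W',k,k
    ho, wo = cols.shape[2], cols.shape[3]
    cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    out = cols @ weight.reshape(f, c * k * k).T
    return out.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)


class Conv2d:
    """Stride-1 convolution, square kernel, He-normal init, optional bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, padding: int,
                 bias: bool, rng: np.random.Generator):
        std = np.sqrt(2.0 / (in_ch * kernel_size * kernel_size))
        self.padding = padding
        self.params = {
            "weight": rng.normal(0, std, (out_ch, in_ch, kernel_size, kernel_size)).astype(_F32)
        }
        if bias:
            self.params["bias"] = np.zeros(out_ch, dtype=_F32)
        self.grads: dict[str, np.ndarray] = {}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = _conv2d_gemm(x, self.params["weight"], self.padding)
        if "bias" in self.params:
            out += self.params["bias"][None, :, None, None]
        if training:
            self._x = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        w = self.params["weight"]
        f, c, k, _ = w.shape
        n, _, h, wd = x.shape
        p = self.padding
        # dW: correlate cached input with dout (recompute im2col; GEMM dominates)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))
        ho, wo = cols.shape[2], cols.shape[3]
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, f)
        self.grads["weight"] = (dmat.T @ cols).reshape(w.shape)
        if "bias" in self.params:
            self.grads["bias"] = dout.sum(axis=(0, 2, 3))
        # dx: full correlation of dout with the flipped, channel-swapped kernel
        w_flip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,F,k,k)
        return _conv2d_gemm(dout, np.ascontiguousarray(w_flip), k - 1 - p)


class BatchNorm2d:
    """Batch normalisation over (N, H, W) per channel with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "weight": np.ones(n_ch, dtype=_F32),
            "bias": np.zeros(n_ch, dtype=_F32),
        }
        self.buffers = {
            "running_mean": np.zeros(n_ch, dtype=_F32),
            "running_var": np.ones(n_ch, dtype=_F32),
        }
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["running_mean"] *= 1 - m
            self.buffers["running_mean"] += m * mean
            self.buffers["running_var"] *= 1 - m
            self.buffers["running_var"] += m * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.params["weight"][None, :, None, None] * xhat
        out += self.params["bias"][None, :, None, None]
        if training:
            self._cache = (xhat, inv_std.astype(_F32))
        return out.astype(_F32, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["weight"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["bias"] = dout.sum(axis=(0, 2, 3))
        g = self.params["weight"]
        dxhat = dout * g[None, :, None, None]
        # dx = (1/m) * inv_std * (m*dxhat - sum(dxhat) - xhat*sum(dxhat*xhat))
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (dxhat - (s1 + xhat * s2) / m) * inv_std[None, :, None, None]
        return dx.astype(_F32, copy=False)


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return dout * mask


class MaxPool2d:
    """2x2 max pooling with stride 2 (even inputs only)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, (n, c, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (idx, (n, c, h, w)), self._cache = self._cache, None
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


class ConvTranspose2d:
    """2x2 transposed convolution with stride 2 (learned 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (in_ch * 4))
        self.params = {
            "weight": rng.normal(0, std, (in_ch, out_ch, 2, 2)).astype(_F32),
            "bias": np.zeros(out_ch, dtype=_F32),
        }
        self.grads: dict[str, np.ndarray] = {}
        self._x = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        wgt = self.params["weight"]
        t = np.tensordot(x, wgt, axes=([1], [0]))  # N,H,W,F,2,2
        out = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, wgt.shape[1], 2 * h, 2 * w)
        out += self.params["bias"][None, :, None, None]
        if training:
            self._x = x
        return out.astype(_F32, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        n, c, h, w = x.shape
        f = self.params["weight"].shape[1]
        dt = dout.reshape(n, f, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # N,H,W,F,2,2
        self.grads["weight"] = np.tensordot(x, dt, axes=([0, 2, 3], [0, 1, 2]))
        self.grads["bias"] = dout.sum(axis=(0, 2, 3))
        dx = np.tensordot(dt, self.params["weight"], axes=([3, 4, 5], [1, 2, 3]))
        return dx.transpose(0, 3, 1, 2).astype(_F32, copy=False)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SGD:
    """SGD with (Nesterov) momentum, matching the common deep-learning update:

    ``v <- mu*v + g``; with Nesterov the applied gradient is ``g + mu*v``.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 momentum: float = 0.9, nesterov: bool = True):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.nesterov = nesterov
        self._velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        mu = self.momentum
        for name, p in self.params.items():
            g = grads[name].astype(p.dtype, copy=False)
            v = self._velocity[name]
            v *= mu
            v += g
            update = g + mu * v if self.nesterov else v
            p -= self.lr * update
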