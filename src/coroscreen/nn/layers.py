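"""NumPy layers with explicit forward/backward passes.

Tensors are float32 in (N, C, D, H, W) layout.  Each layer caches what its
backward pass needs; parameter gradients accumulate in ``.grads`` keyed like
``.params``.  Convolution uses im2col + BLAS matmul, with col2im scatter as
a short loop over kernel offsets — fast enough on CPU for the compact
volumes this package trains on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3d", "BatchNorm3d", "ReLU", "SEGate", "Linear", "GlobalAvgPool", "kaiming_normal"]


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He initialization for ReLU networks: N(0, sqrt(2 / fan_in))."""
    return (rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)).astype(np.float32)


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def zero_grad(self):
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


class Conv3d(Layer):
    """3D convolution, cubic kernel, symmetric zero padding, no bias."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int | None = None):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = (kernel // 2) if pad is None else pad
        fan_in = c_in * kernel**3
        self.params["W"] = kaiming_normal(rng, (c_out, c_in, kernel, kernel, kernel), fan_in)
        self.zero_grad()

    def _im2col(self, x):
        p, k, s = self.pad, self.k, self.stride
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        v = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        n, c, do, ho, wo = v.shape[:5]
        cols = np.ascontiguousarray(v.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            n, do * ho * wo, c * k**3)
        return cols, (do, ho, wo), x.shape[2:]

    def forward(self, x, train: bool = False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        cols, out_sp, padded_sp = self._im2col(x)
        wmat = self.params["W"].reshape(self.c_out, -1)
        y = cols @ wmat.T                                   # (N, V, Cout)
        n = x.shape[0]
        self._cache = (cols, out_sp, padded_sp, x.shape)
        return np.ascontiguousarray(y.transpose(0, 2, 1)).reshape(n, self.c_out, *out_sp)

    def backward(self, dy):
        cols, (do, ho, wo), padded_sp, x_shape = self._cache
        n, c, k, s, p = x_shape[0], self.c_in, self.k, self.stride, self.pad
        dy_flat = np.ascontiguousarray(dy.reshape(n, self.c_out, -1).transpose(0, 2, 1))  # (N,V,Cout)
        wmat = self.params["W"].reshape(self.c_out, -1)
        dW = np.tensordot(dy_flat, cols, axes=([0, 1], [0, 1]))       # (Cout, C*k^3)
        self.grads["W"] += dW.reshape(self.params["W"].shape)
        dcols = dy_flat @ wmat                                         # (N, V, C*k^3)
        dcols = dcols.reshape(n, do, ho, wo, c, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        dxp = np.zeros((n, c) + padded_sp, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, :, i:i + do * s:s, j:j + ho * s:s, l:l + wo * s:s] += dcols[..., i, j, l]
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class BatchNorm3d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.zero_grad()

    def forward(self, x, train: bool = False):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean[None, :, None, None, None]) / std[None, :, None, None, None]
        self._cache = (xhat, std, train)
        g = self.params["gamma"][None, :, None, None, None]
        b = self.params["beta"][None, :, None, None, None]
        return (g * xhat + b).astype(np.float32)

    def backward(self, dy):
        xhat, std, train = self._cache
        axes = (0, 2, 3, 4)
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None, None]
        dxhat = dy * g
        if not train:
            # eval mode: running stats are constants w.r.t. the input
            return (dxhat / std[None, :, None, None, None]).astype(np.float32)
        mean_dxhat = dxhat.mean(axis=axes)[None, :, None, None, None]
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes)[None, :, None, None, None]
        return ((dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
                / std[None, :, None, None, None]).astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class SEGate(Layer):
    """Squeeze-and-excitation channel gate: GAP -> FC -> ReLU -> FC -> sigmoid -> scale."""

    def __init__(self, rng, c: int, reduction: int = 4):
        super().__init__()
        hidden = max(c // reduction, 1)
        self.c, self.hidden = c, hidden
        self.params["W1"] = kaiming_normal(rng, (hidden, c), c)
        self.params["b1"] = np.zeros(hidden, dtype=np.float32)
        self.params["W2"] = kaiming_normal(rng, (c, hidden), hidden)
        self.params["b2"] = np.zeros(c, dtype=np.float32)
        self.zero_grad()

    def forward(self, x, train: bool = False):
        z = x.mean(axis=(2, 3, 4))                      # (N, C)
        h_pre = z @ self.params["W1"].T + self.params["b1"]
        h = np.maximum(h_pre, 0.0)
        g = 1.0 / (1.0 + np.exp(-(h @ self.params["W2"].T + self.params["b2"])))
        self._cache = (x, z, h_pre, h, g)
        self.gate = g
        return (x * g[:, :, None, None, None]).astype(np.float32)

    def backward(self, dy):
        x, z, h_pre, h, g = self._cache
        v = x.shape[2] * x.shape[3] * x.shape[4]
        dg = (dy * x).sum(axis=(2, 3, 4)) * g * (1 - g)     # (N, C), through sigmoid
        self.grads["W2"] += dg.T @ h
        self.grads["b2"] += dg.sum(axis=0)
        dh = (dg @ self.params["W2"]) * (h_pre > 0)
        self.grads["W1"] += dh.T @ z
        self.grads["b1"] += dh.sum(axis=0)
        dz = dh @ self.params["W1"]                          # (N, C)
        dx = dy * g[:, :, None, None, None] + dz[:, :, None, None, None] / v
        return dx.astype(np.float32)


class Linear(Layer):
    def __init__(self, rng, n_in: int, n_out: int):
        super().__init__()
        self.params["W"] = kaiming_normal(rng, (n_out, n_in), n_in)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)
        self.zero_grad()

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads["W"] += dy.T @ self._x
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"]


class GlobalAvgPool(Layer):
    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        n, c, d, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None, None] / (d * h * w),
                               self._shape).astype(np.float32)
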