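"""Numpy layers with exact manual backprop.

Convolutions are stride-1 with "same" zero padding (an even 4x4 kernel pads
asymmetrically, one voxel before and two after, per axis, times the dilation)
so every layer preserves the 24x24 spatial extent.

Data layout is channels-last, (N, H, W, C) — a patch is 24 x 24 x T with the
dynamic frames stacked along the last axis. Weights are stored HWIO
(k, k, c_in, c_out), so im2col is a set of contiguous tap copies and both
passes reduce to BLAS matmuls; the input-gradient pass is the transposed
convolution written as per-tap accumulation. The column matrix built in a
training-mode forward pass is cached for the backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv2D", "DepthwiseConv2D", "ReLU"]


def _same_pad(k: int, d: int):
    """(before, after) zero padding preserving extent for kernel k, dilation d."""
    total = d * (k - 1)
    return total // 2, total - total // 2


class Layer:
    """Minimal layer protocol: forward caches, backward returns dX."""

    def params(self):
        return {}

    def grads(self):
        return {}

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 2D convolution, optionally dilated, shape preserving.

    A 1x1 kernel doubles as a per-voxel fully connected layer and takes a
    pure-matmul fast path.
    """

    def __init__(self, c_in, c_out, kernel=4, dilation=1, rng=None,
                 dtype=np.float64):
        self.c_in, self.c_out = c_in, c_out
        self.k, self.d = kernel, dilation
        fan_in = c_in * kernel * kernel
        rng = rng or np.random.default_rng(0)
        # He-normal initialization for rectifier networks
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (kernel, kernel, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None
        self._cols = None

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def _pad(self, x):
        p0, p1 = _same_pad(self.k, self.d)
        return np.pad(x, ((0, 0), (p0, p1), (p0, p1), (0, 0))), p0

    def _im2col(self, xp, n, h, w):
        """(N, Hp, Wp, C) -> (N*H*W, k*k*C) with taps contiguous-sliced."""
        cols = np.empty((n, h, w, self.k * self.k, self.c_in),
                        dtype=xp.dtype)
        t = 0
        for i in range(self.k):
            for j in range(self.k):
                cols[:, :, :, t, :] = xp[:, i * self.d : i * self.d + h,
                                         j * self.d : j * self.d + w, :]
                t += 1
        return cols.reshape(n * h * w, -1)

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        if train:
            self._x = x
        if self.k == 1:
            wm = self.w.reshape(self.c_in, self.c_out)
            y = x.reshape(-1, c) @ wm
            return (y + self.b).reshape(n, h, w, self.c_out)
        xp, _ = self._pad(x)
        wm = self.w.reshape(-1, self.c_out)
        cols = self._im2col(xp, n, h, w)
        if train:
            self._cols = cols
        y = cols @ wm
        return (y + self.b).reshape(n, h, w, self.c_out)

    def backward(self, dy):
        x = self._x
        n, h, w, c = x.shape
        dym = dy.reshape(-1, self.c_out)
        if self.k == 1:
            wm = self.w.reshape(self.c_in, self.c_out)
            self.dw[...] = (x.reshape(-1, c).T @ dym).reshape(self.w.shape)
            self.db[...] = dym.sum(axis=0)
            return (dym @ wm.T).reshape(x.shape)
        p0, _ = _same_pad(self.k, self.d)
        cols = self._cols
        self.dw[...] = (cols.T @ dym).reshape(self.w.shape)
        self.db[...] = dym.sum(axis=0)
        # transposed convolution: scatter each tap's contribution back
        dcols = (dym @ self.w.reshape(-1, self.c_out).T).reshape(
            n, h, w, self.k * self.k, self.c_in)
        pt = self.d * (self.k - 1)
        dxp = np.zeros((n, h + pt, w + pt, self.c_in), dtype=x.dtype)
        t = 0
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i * self.d : i * self.d + h,
                    j * self.d : j * self.d + w, :] += dcols[:, :, :, t, :]
                t += 1
        return dxp[:, p0 : p0 + h, p0 : p0 + w, :]


class DepthwiseConv2D(Layer):
    """Per-channel (grouped) 4x4 convolution: each input frame filtered
    independently — the first-layer temporal-feature extractor."""

    def __init__(self, channels, kernel=4, rng=None, dtype=np.float64):
        self.c = channels
        self.k = kernel
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / (kernel * kernel)),
                            (kernel, kernel, channels)).astype(dtype)
        self.b = np.zeros(channels, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if c != self.c:
            raise ValueError(f"expected {self.c} channels, got {c}")
        if train:
            self._x = x
        p0, p1 = _same_pad(self.k, 1)
        xp = np.pad(x, ((0, 0), (p0, p1), (p0, p1), (0, 0)))
        y = np.zeros_like(x)
        for i in range(self.k):
            for j in range(self.k):
                y += xp[:, i : i + h, j : j + w, :] * self.w[i, j]
        return y + self.b

    def backward(self, dy):
        x = self._x
        n, h, w, c = x.shape
        p0, p1 = _same_pad(self.k, 1)
        xp = np.pad(x, ((0, 0), (p0, p1), (p0, p1), (0, 0)))
        dxp = np.zeros_like(xp)
        for i in range(self.k):
            for j in range(self.k):
                self.dw[i, j] = np.einsum(
                    "nhwc,nhwc->c", dy, xp[:, i : i + h, j : j + w, :],
                    optimize=True)
                dxp[:, i : i + h, j : j + w, :] += dy * self.w[i, j]
        self.db[...] = dy.sum(axis=(0, 1, 2))
        return dxp[:, p0 : p0 + h, p0 : p0 + w, :]


class ReLU(Layer):
    """Rectifier f(x) = max(0, x)."""

    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask
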