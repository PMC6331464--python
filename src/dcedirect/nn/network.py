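"""The dual-pathway dilated-convolution network.

Input: a 24 x 24 patch with the dynamic frames stacked as channels.
First layer: each frame is filtered independently by a 4x4 kernel
(depthwise convolution) and the frames are then aggregated across channels by
learned 1x1 weights into ``filters`` feature maps.  Two parallel pathways
follow: a local pathway of standard 4x4 convolutions and a global pathway of
dilated 4x4 convolutions (dilation factors 2, 4, 8) that enlarges the
receptive field for spatial context.  The pathways are concatenated and fused
by a 4x4 convolution with ``concat_filters`` filters, after which per-voxel
fully connected layers (1x1 convolutions, hidden widths 256 and 128 by
default) map the multi-scale features to the ``n_params`` output channels.
ReLU follows every layer except the output; all convolutions are stride-1,
zero padded, so each layer preserves the 24 x 24 extent and the output is
24 x 24 x n_params.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .layers import Conv2D, DepthwiseConv2D, ReLU

__all__ = ["NetworkSpec", "DirectNet", "build_network"]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters (defaults: the full-size network)."""

    n_frames: int = 21
    patch: int = 24
    kernel: int = 4
    filters: int = 32
    concat_filters: int = 64
    dense: Tuple[int, int] = (256, 128)
    dilations: Tuple[int, ...] = (2, 4, 8)
    local_depth: int = 3

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.patch < self.kernel:
            raise ValueError("invalid network spec")


class DirectNet:
    """Maps a (N, 24, 24, T) signal patch batch to (N, 24, 24, n_params)."""

    def __init__(self, spec: NetworkSpec, n_params: int, rng=None,
                 dtype=np.float64):
        self.spec = spec
        self.n_params = n_params
        self.dtype = dtype
        rng = rng or np.random.default_rng(0)
        f = spec.filters
        k = spec.kernel

        self.dw = DepthwiseConv2D(spec.n_frames, kernel=k, rng=rng,
                                  dtype=dtype)
        self.agg = Conv2D(spec.n_frames, f, kernel=1, rng=rng, dtype=dtype)
        self.agg_relu = ReLU()
        self.local = []
        for _ in range(spec.local_depth):
            self.local += [Conv2D(f, f, kernel=k, dilation=1, rng=rng,
                                  dtype=dtype), ReLU()]
        self.globl = []
        for d in spec.dilations:
            self.globl += [Conv2D(f, f, kernel=k, dilation=d, rng=rng,
                                  dtype=dtype), ReLU()]
        self.fuse = Conv2D(2 * f, spec.concat_filters, kernel=k, rng=rng,
                           dtype=dtype)
        self.fuse_relu = ReLU()
        self.head = []
        widths = (spec.concat_filters,) + tuple(spec.dense)
        for c_in, c_out in zip(widths[:-1], widths[1:]):
            self.head += [Conv2D(c_in, c_out, kernel=1, rng=rng, dtype=dtype),
                          ReLU()]
        self.head.append(Conv2D(widths[-1], n_params, kernel=1, rng=rng,
                                dtype=dtype))

    # -- parameter plumbing -------------------------------------------------

    def layers(self):
        return ([self.dw, self.agg, self.agg_relu] + self.local + self.globl
                + [self.fuse, self.fuse_relu] + self.head)

    def parameters(self):
        """Flat list of (layer_index, name, array) views."""
        out = []
        for i, layer in enumerate(self.layers()):
            for name, arr in layer.params().items():
                out.append((i, name, arr))
        return out

    def gradients(self):
        out = []
        for i, layer in enumerate(self.layers()):
            for name, arr in layer.grads().items():
                out.append((i, name, arr))
        return out

    def get_weights(self):
        return [arr.copy() for _, _, arr in self.parameters()]

    def set_weights(self, weights):
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for (_, _, arr), w in zip(params, weights):
            if arr.shape != w.shape:
                raise ValueError("weight shape mismatch")
            arr[...] = w

    # -- forward / backward -------------------------------------------------

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[-1] != self.spec.n_frames:
            raise ValueError(
                f"expected (N, H, W, {self.spec.n_frames}) input, got "
                f"{x.shape}"
            )
        h = self.dw.forward(x, train)
        h = self.agg_relu.forward(self.agg.forward(h, train), train)
        hl = h
        for layer in self.local:
            hl = layer.forward(hl, train)
        hg = h
        for layer in self.globl:
            hg = layer.forward(hg, train)
        cat = np.concatenate([hl, hg], axis=-1)
        z = self.fuse_relu.forward(self.fuse.forward(cat, train), train)
        for layer in self.head:
            z = layer.forward(z, train)
        return z

    def backward(self, dy):
        """Backpropagate dLoss/dOutput; gradients land in each layer."""
        g = np.ascontiguousarray(dy, dtype=self.dtype)
        for layer in reversed(self.head):
            g = layer.backward(g)
        g = self.fuse.backward(self.fuse_relu.backward(g))
        f = self.spec.filters
        gl, gg = g[..., :f], g[..., f:]
        for layer in reversed(self.local):
            gl = layer.backward(gl)
        for layer in reversed(self.globl):
            gg = layer.backward(gg)
        g = gl + gg
        g = self.agg.backward(self.agg_relu.backward(g))
        return self.dw.backward(g)

    def predict_patches(self, x, batch=256):
        """Inference in batches; returns (N, H, W, n_params)."""
        outs = []
        for i in range(0, x.shape[0], batch):
            outs.append(self.forward(x[i : i + batch], train=False))
        return np.concatenate(outs, axis=0)


def build_network(spec: NetworkSpec, n_params: int, seed: int = 0,
                  dtype=np.float32) -> DirectNet:
    """Seeded construction of an untrained network."""
    return DirectNet(spec, n_params, rng=np.random.default_rng(seed),
                     dtype=dtype)
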