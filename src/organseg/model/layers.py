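"""Minimal 3D convolutional layer zoo with explicit backpropagation.

Everything operates on single samples shaped ``(channels, nx, ny, nz)`` in
float32.  Convolutions are *valid* (no padding): the output shrinks by the
kernel margin, which is what makes tiled inference exactly composable.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3d", "AvgPool2", "Upsample2", "centre_crop", "uncrop_grad"]


class Conv3d:
    """Valid 3D convolution (cross-correlation) with optional fused ReLU.

    Weights use He initialisation scaled to the fan-in.  ``kernel`` is a
    per-axis size triple; kernels like (3, 3, 1) are how the networks keep
    a near-cubic millimetre receptive field on anisotropic voxels.
    """

    def __init__(self, cin: int, cout: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator, relu: bool = True):
        self.cin, self.cout, self.kernel = cin, cout, tuple(int(k) for k in kernel)
        fan_in = cin * int(np.prod(self.kernel))
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (cout, cin) + self.kernel).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.relu = relu
        self._x = None
        self._relu_mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[0] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[0]}")
        for a in range(3):
            if x.shape[1 + a] < self.kernel[a]:
                raise ValueError(
                    f"input spatial size {x.shape[1:]} smaller than kernel {self.kernel}"
                )
        win = sliding_window_view(x, self.kernel, axis=(1, 2, 3))
        y = np.tensordot(self.w, win, axes=([1, 2, 3, 4], [0, 4, 5, 6]))
        y += self.b[:, None, None, None]
        if self.relu:
            mask = y > 0
            y *= mask
        if train:
            self._x = x
            self._relu_mask = mask if self.relu else None
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self.relu:
            gy = gy * self._relu_mask
        x = self._x
        win = sliding_window_view(x, self.kernel, axis=(1, 2, 3))
        self.gw += np.tensordot(gy, win, axes=([1, 2, 3], [1, 2, 3]))
        self.gb += gy.sum(axis=(1, 2, 3))
        # gradient wrt input: full correlation with spatially flipped kernels
        pads = [(0, 0)] + [(k - 1, k - 1) for k in self.kernel]
        gpad = np.pad(gy, pads)
        win2 = sliding_window_view(gpad, self.kernel, axis=(1, 2, 3))
        wf = self.w[:, :, ::-1, ::-1, ::-1]
        gx = np.tensordot(wf.transpose(1, 0, 2, 3, 4), win2,
                          axes=([1, 2, 3, 4], [0, 4, 5, 6]))
        return np.ascontiguousarray(gx, dtype=np.float32)

    def zero_grad(self) -> None:
        self.gw[...] = 0
        self.gb[...] = 0

    def parameters(self):
        yield self.w, self.gw
        yield self.b, self.gb


class AvgPool2:
    """2x2x2 average pooling with stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, nx, ny, nz = x.shape
        if nx % 2 or ny % 2 or nz % 2:
            raise ValueError(f"pooling needs even spatial dims, got {x.shape[1:]}")
        y = x.reshape(c, nx // 2, 2, ny // 2, 2, nz // 2, 2).mean(axis=(2, 4, 6))
        return y.astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = np.repeat(np.repeat(np.repeat(gy, 2, axis=1), 2, axis=2), 2, axis=3)
        return (g / 8.0).astype(np.float32)


class Upsample2:
    """Nearest-neighbour upsampling by 2 along each spatial axis."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, nx, ny, nz = gy.shape
        return gy.reshape(c, nx // 2, 2, ny // 2, 2, nz // 2, 2).sum(axis=(2, 4, 6))


def centre_crop(x: np.ndarray, target_spatial: tuple[int, int, int]) -> np.ndarray:
    """Symmetric centre crop of the spatial axes; crop amounts must be even."""
    slices = [slice(None)]
    for a in range(3):
        diff = x.shape[1 + a] - target_spatial[a]
        if diff < 0:
            raise ValueError("cannot crop to a larger size")
        if diff % 2:
            raise ValueError(f"asymmetric crop on axis {a} ({diff} voxels)")
        slices.append(slice(diff // 2, diff // 2 + target_spatial[a]))
    return x[tuple(slices)]


def uncrop_grad(gy: np.ndarray, source_spatial: tuple[int, int, int]) -> np.ndarray:
    """Adjoint of :func:`centre_crop`: zero-pad the gradient back out."""
    pads = [(0, 0)]
    for a in range(3):
        diff = source_spatial[a] - gy.shape[1 + a]
        pads.append((diff // 2, diff - diff // 2))
    return np.pad(gy, pads)
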