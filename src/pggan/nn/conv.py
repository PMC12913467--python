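"""Strided 3D convolution primitives (forward and both gradients).

Padding follows the 'same' convention for strided convolution: each spatial
axis of size n maps to ceil(n / stride), with the total padding split
low/high (extra voxel on the high side).  The transposed convolution used by
the decoder is the exact adjoint of this operation, so a stride-2 deconv
always produces exactly twice the input extent.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "same_pads",
    "conv3d_forward",
    "conv3d_input_grad",
    "conv3d_weight_grad",
]


def same_pads(size: int, k: int, stride: int) -> tuple[int, int]:
    """(low, high) padding so that output extent is ceil(size / stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    low = total // 2
    return low, total - low


def _pad_input(x: np.ndarray, kernel: tuple[int, int, int], stride: int):
    pads = [same_pads(s, k, stride) for s, k in zip(x.shape[2:], kernel)]
    xp = np.pad(x, [(0, 0), (0, 0)] + pads)
    return xp, pads


def conv3d_forward(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    """x: (N, C, D, H, W); w: (O, C, kd, kh, kw) -> (N, O, D', H', W')."""
    kernel = w.shape[2:]
    xp, _ = _pad_input(x, kernel, stride)
    win = sliding_window_view(xp, kernel, axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]
    # (N,C,D',H',W',kd,kh,kw) x (O,C,kd,kh,kw) -> (N,O,D',H',W')
    return np.einsum("ncdhwijk,ocijk->nodhw", win, w, optimize=True)


def conv3d_input_grad(
    dy: np.ndarray, w: np.ndarray, x_shape: tuple[int, ...], stride: int
) -> np.ndarray:
    """Gradient w.r.t. the convolution input (also the deconv forward map)."""
    kernel = w.shape[2:]
    pads = [same_pads(s, k, stride) for s, k in zip(x_shape[2:], kernel)]
    padded_shape = [s + lo + hi for s, (lo, hi) in zip(x_shape[2:], pads)]
    n = x_shape[0]
    dxp = np.zeros((n, x_shape[1], *padded_shape), dtype=dy.dtype)
    # single large contraction, then scatter per kernel offset
    # t: (N, D', H', W', C, kd, kh, kw)
    t = np.tensordot(dy, w, axes=([1], [0])).transpose(0, 4, 1, 2, 3, 5, 6, 7)
    do, ho, wo = dy.shape[2:]
    for i in range(kernel[0]):
        for j in range(kernel[1]):
            for k in range(kernel[2]):
                dxp[
                    :,
                    :,
                    i : i + stride * do : stride,
                    j : j + stride * ho : stride,
                    k : k + stride * wo : stride,
                ] += t[:, :, :, :, :, i, j, k]
    sl = tuple(slice(lo, lo + s) for s, (lo, _) in zip(x_shape[2:], pads))
    return dxp[:, :, sl[0], sl[1], sl[2]]


def conv3d_weight_grad(
    x: np.ndarray, dy: np.ndarray, w_shape: tuple[int, ...], stride: int
) -> np.ndarray:
    """Gradient w.r.t. the convolution weights."""
    kernel = w_shape[2:]
    xp, _ = _pad_input(x, kernel, stride)
    win = sliding_window_view(xp, kernel, axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]
    return np.einsum("ncdhwijk,nodhw->ocijk", win, dy, optimize=True)
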