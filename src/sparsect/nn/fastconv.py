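"""Numba kernels for convolution data movement and fused batch-norm.

The GEMMs go through BLAS; these kernels gather image windows into column
matrices (with implicit zero padding), scatter column gradients back, and
fuse the batch-norm passes.  They exist because on a single core the NumPy
equivalents are dominated by large temporary allocations and strided copies.
"""

from __future__ import annotations

import ctypes

import numba
import numpy as np

__all__ = ["im2col_into", "col2im_into", "bn_stats", "bn_apply",
           "bn_backward", "tune_allocator"]


def tune_allocator(threshold: int = 1 << 30) -> bool:
    """Raise glibc's mmap threshold so large, frequently recycled conv
    buffers are served from the heap instead of being mmap'ed and unmapped
    on every call (first-touch page faults dominate otherwise)."""
    try:
        libc = ctypes.CDLL("libc.so.6", use_errno=True)
        M_MMAP_THRESHOLD = -3
        return bool(libc.mallopt(M_MMAP_THRESHOLD, threshold))
    except Exception:
        return False


@numba.njit(cache=True, fastmath=True)
def im2col_into(x: np.ndarray, k: int, col: np.ndarray) -> None:
    """im2col with implicit zero 'same' padding.

    x: (m, H, W, C) float32; col: preallocated (m*H*W, k*k*C).
    Column order is (dy, dx, channel).
    """
    m, H, W, C = x.shape
    p = k // 2
    for n in range(m):
        base = n * H * W
        for i in range(H):
            for j in range(W):
                row = base + i * W + j
                for dy in range(k):
                    yy = i + dy - p
                    yin = 0 <= yy < H
                    for dx in range(k):
                        xx = j + dx - p
                        idx = (dy * k + dx) * C
                        if yin and 0 <= xx < W:
                            src = x[n, yy, xx]
                            for c in range(C):
                                col[row, idx + c] = src[c]
                        else:
                            for c in range(C):
                                col[row, idx + c] = 0.0


@numba.njit(cache=True, fastmath=True)
def col2im_into(dcol: np.ndarray, k: int, dx: np.ndarray) -> None:
    """Adjoint of :func:`im2col_into`; accumulates into zeroed ``dx``."""
    m, H, W, C = dx.shape
    p = k // 2
    dx[...] = 0.0
    for n in range(m):
        base = n * H * W
        for i in range(H):
            for j in range(W):
                row = base + i * W + j
                for dy in range(k):
                    yy = i + dy - p
                    if yy < 0 or yy >= H:
                        continue
                    for dx_ in range(k):
                        xx = j + dx_ - p
                        if xx < 0 or xx >= W:
                            continue
                        idx = (dy * k + dx_) * C
                        dst = dx[n, yy, xx]
                        for c in range(C):
                            dst[c] += dcol[row, idx + c]


@numba.njit(cache=True, fastmath=True)
def bn_stats(x: np.ndarray):
    """Per-channel mean and (biased) variance over (N, H, W) in one pass."""
    N, H, W, C = x.shape
    s = np.zeros(C, np.float64)
    ss = np.zeros(C, np.float64)
    for n in range(N):
        for i in range(H):
            for j in range(W):
                v = x[n, i, j]
                for c in range(C):
                    s[c] += v[c]
                    ss[c] += v[c] * v[c]
    m = N * H * W
    mean = (s / m).astype(np.float32)
    var = (ss / m - (s / m) ** 2).astype(np.float32)
    return mean, var


@numba.njit(cache=True, fastmath=True)
def bn_apply(x, mean, invstd, gamma, beta, xhat, y) -> None:
    """y = gamma * (x - mean) * invstd + beta, storing xhat for backward."""
    N, H, W, C = x.shape
    for n in range(N):
        for i in range(H):
            for j in range(W):
                xv = x[n, i, j]
                xh = xhat[n, i, j]
                yv = y[n, i, j]
                for c in range(C):
                    h = (xv[c] - mean[c]) * invstd[c]
                    xh[c] = h
                    yv[c] = gamma[c] * h + beta[c]


@numba.njit(cache=True, fastmath=True)
def bn_backward(dy, xhat, invstd, gamma, dx):
    """Training-mode batch-norm backward; returns (dgamma, dbeta)."""
    N, H, W, C = dy.shape
    M = N * H * W
    sum_dy = np.zeros(C, np.float64)
    sum_dy_xhat = np.zeros(C, np.float64)
    for n in range(N):
        for i in range(H):
            for j in range(W):
                g = dy[n, i, j]
                h = xhat[n, i, j]
                for c in range(C):
                    sum_dy[c] += g[c]
                    sum_dy_xhat[c] += g[c] * h[c]
    a = np.empty(C, np.float32)
    for c in range(C):
        a[c] = gamma[c] * invstd[c] / M
    s1 = sum_dy.astype(np.float32)
    s2 = sum_dy_xhat.astype(np.float32)
    for n in range(N):
        for i in range(H):
            for j in range(W):
                g = dy[n, i, j]
                h = xhat[n, i, j]
                d = dx[n, i, j]
                for c in range(C):
                    d[c] = a[c] * (M * g[c] - s1[c] - h[c] * s2[c])
    return s2, s1
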