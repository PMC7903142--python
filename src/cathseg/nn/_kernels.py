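"""Fused elementwise kernels for the batch-norm hot path.

Batch normalization is memory-bound: the naive numpy formulation walks
each feature map half a dozen times per pass.  These numba kernels do
the same arithmetic in one or two walks.  numpy fallbacks with
identical semantics are used when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every forward pass
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco


@njit(fastmath=True, cache=False)
def _bn_stats_nb(x2d):
    """Per-channel sum and sum of squares over a (rows, C) view."""
    rows, c = x2d.shape
    s = np.zeros(c, dtype=np.float64)
    ss = np.zeros(c, dtype=np.float64)
    for i in range(rows):
        for j in range(c):
            v = np.float64(x2d[i, j])
            s[j] += v
            ss[j] += v * v
    return s, ss


@njit(fastmath=True, cache=False)
def _bn_forward_nb(x2d, scale, shift, out2d):
    rows, c = x2d.shape
    for i in range(rows):
        for j in range(c):
            out2d[i, j] = x2d[i, j] * scale[j] + shift[j]


@njit(fastmath=True, cache=False)
def _bn_backward_reduce_nb(dy2d, x2d, mean, inv):
    """Per-channel sum(dy) and sum(dy * xhat) in one walk."""
    rows, c = dy2d.shape
    sdy = np.zeros(c, dtype=np.float64)
    sdyx = np.zeros(c, dtype=np.float64)
    for i in range(rows):
        for j in range(c):
            d = np.float64(dy2d[i, j])
            sdy[j] += d
            sdyx[j] += d * np.float64((x2d[i, j] - mean[j]) * inv[j])
    return sdy, sdyx


@njit(fastmath=True, cache=False)
def _bn_backward_dx_nb(dy2d, x2d, mean, inv, gamma, mean_dy, mean_dyx, out2d):
    """dx = gamma*inv * (dy - mean_dy - xhat * mean_dyx), one walk."""
    rows, c = dy2d.shape
    for i in range(rows):
        for j in range(c):
            xhat = (x2d[i, j] - mean[j]) * inv[j]
            out2d[i, j] = (
                gamma[j] * inv[j] * (dy2d[i, j] - mean_dy[j] - xhat * mean_dyx[j])
            )


@njit(fastmath=True, cache=False)
def _im2col_nb(xp, stride, k, cols):
    """Gather k x k windows of padded NHWC ``xp`` into (N*OH*OW, C*k*k)
    with column order (C, ki, kj)."""
    n, hp, wp, c = xp.shape
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    row = 0
    for b in range(n):
        for i in range(oh):
            for j in range(ow):
                i0 = i * stride
                j0 = j * stride
                col = 0
                for ch in range(c):
                    for ki in range(k):
                        for kj in range(k):
                            cols[row, col] = xp[b, i0 + ki, j0 + kj, ch]
                            col += 1
                row += 1


@njit(fastmath=True, cache=False)
def _col2im_nb(cols, stride, k, out):
    """Adjoint of :func:`_im2col_nb`: scatter-add windows into ``out``."""
    n, hp, wp, c = out.shape
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    row = 0
    for b in range(n):
        for i in range(oh):
            for j in range(ow):
                i0 = i * stride
                j0 = j * stride
                col = 0
                for ch in range(c):
                    for ki in range(k):
                        for kj in range(k):
                            out[b, i0 + ki, j0 + kj, ch] += cols[row, col]
                            col += 1
                row += 1


def im2col(xp: np.ndarray, k: int, stride: int):
    """Windows of a padded NHWC tensor as a (N*OH*OW, C*k*k) matrix."""
    n, hp, wp, c = xp.shape
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    if HAVE_NUMBA:
        cols = np.empty((n * oh * ow, c * k * k), dtype=np.float32)
        _im2col_nb(xp, stride, k, cols)
        return cols, oh, ow
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(xp, (k, k), axis=(1, 2))
    if stride > 1:
        win = win[:, ::stride, ::stride]
    return np.ascontiguousarray(win).reshape(n * oh * ow, c * k * k), oh, ow


def col2im(cols: np.ndarray, x_shape, k: int, stride: int) -> np.ndarray:
    """Scatter-add (N*OH*OW, C*k*k) windows back into an NHWC tensor."""
    out = np.zeros(x_shape, dtype=np.float32)
    if HAVE_NUMBA:
        _col2im_nb(cols, stride, k, out)
        return out
    n, h, w, c = x_shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    cols = cols.reshape(n, oh, ow, c, k, k)
    for ki in range(k):
        for kj in range(k):
            out[:, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride, :] += cols[
                :, :, :, :, ki, kj
            ]
    return out


def bn_stats(x: np.ndarray):
    """Per-channel mean and variance of an NHWC tensor."""
    x2d = x.reshape(-1, x.shape[-1])
    if HAVE_NUMBA:
        s, ss = _bn_stats_nb(x2d)
        m = x2d.shape[0]
        mean = s / m
        var = ss / m - mean**2
        return mean.astype(np.float32), np.maximum(var, 0.0).astype(np.float32)
    return (
        x2d.mean(axis=0, dtype=np.float64).astype(np.float32),
        x2d.var(axis=0, dtype=np.float64).astype(np.float32),
    )


def bn_forward(x: np.ndarray, scale: np.ndarray, shift: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    if HAVE_NUMBA:
        _bn_forward_nb(x.reshape(-1, x.shape[-1]), scale, shift, out.reshape(-1, x.shape[-1]))
        return out
    np.multiply(x, scale, out=out)
    out += shift
    return out


def bn_backward(dy, x, mean, inv, gamma, batch_mode: bool):
    """Returns (sum_dy, sum_dy_xhat, dx)."""
    c = dy.shape[-1]
    dy2d = dy.reshape(-1, c)
    x2d = x.reshape(-1, c)
    m = dy2d.shape[0]
    if HAVE_NUMBA:
        sdy, sdyx = _bn_backward_reduce_nb(dy2d, x2d, mean, inv)
    else:
        xhat = (x2d - mean) * inv
        sdy = dy2d.sum(axis=0, dtype=np.float64)
        sdyx = (dy2d * xhat).sum(axis=0, dtype=np.float64)
    if not batch_mode:
        dx = dy * (gamma * inv)
        return sdy, sdyx, dx.astype(np.float32, copy=False)
    mean_dy = (sdy / m).astype(np.float32)
    mean_dyx = (sdyx / m).astype(np.float32)
    dx = np.empty_like(dy)
    if HAVE_NUMBA:
        _bn_backward_dx_nb(
            dy2d, x2d, mean, inv, gamma, mean_dy, mean_dyx, dx.reshape(-1, c)
        )
    else:
        xhat = (x.reshape(-1, c) - mean) * inv
        dx2d = (gamma * inv) * (dy2d - mean_dy - xhat * mean_dyx)
        dx.reshape(-1, c)[:] = dx2d
    return sdy, sdyx, dx
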