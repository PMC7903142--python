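"""Minimal NHWC convolutional-network layers with explicit backprop.

Implements exactly the layer vocabulary the light U-Net needs: 3x3
convolution (stride 1 or 2, "same" padding), its stride-2 transpose,
batch normalization, ReLU and sigmoid.  All tensors are float32 arrays
in (batch, height, width, channels) layout.

Stride-1 convolutions use an allocation-free scheme: on the flat view
of the zero-padded NHWC tensor each kernel tap is a constant row
offset, so the convolution is nine BLAS ``sgemm`` accumulations over
contiguous views.  Values computed in the padded border are cropped;
because the padding is zero, no wrap-around contamination reaches the
retained rows.  Stride-2 convolutions and transposed convolutions run
at half/quarter resolution where an explicit im2col is cheap.

Each layer caches what its backward pass needs and releases the cache
afterwards, so peak memory stays bounded by one batch in flight.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg.blas import sgemm

from ._kernels import bn_backward, bn_forward, bn_stats, col2im, im2col

__all__ = ["Layer", "Conv2d", "ConvTranspose2d", "BatchNorm2d", "ReLU", "Sigmoid"]


def _gemm_acc(out2d: np.ndarray, a2d: np.ndarray, b2d: np.ndarray, beta: float = 1.0) -> None:
    """``out2d += a2d @ b2d`` via BLAS on C-contiguous float32 arrays.

    Runs the computation in the transposed (column-major) world so no
    operand is copied: ``out.T = b.T @ a.T`` with all three transposes
    being Fortran-contiguous views.
    """
    sgemm(1.0, b2d.T, a2d.T, beta=beta, c=out2d.T, overwrite_c=1)


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))


class Layer:
    """Base class: named, optionally trainable, holds params and grads."""

    kind = "layer"

    def __init__(self, name: str):
        self.name = name
        self.trainable = True
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, "same" padding, stride 1 or 2, He-initialised.

    The weight matrix has shape (c_in * k * k, c_out) with row order
    (tap_i, tap_j, c_in) for stride 1 and (c_in, tap_i, tap_j) for
    stride 2 (the im2col window order); ``n_params`` is layout-free.
    """

    kind = "conv"

    def __init__(self, name, c_in, c_out, k=3, stride=1, rng=None):
        super().__init__(name)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (k * k * c_in))
        self.params["W"] = rng.normal(0.0, std, size=(c_in * k * k, c_out)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    @property
    def pad(self) -> int:
        return self.k // 2

    def _taps(self):
        """Weight slabs per kernel tap for the stride-1 offset scheme."""
        return self.params["W"].reshape(self.k * self.k, self.c_in, self.c_out)

    def forward(self, x, training):
        if self.stride == 1:
            return self._forward_s1(x, training)
        p = self.pad
        xp = _pad_hw(x, p)
        cols, oh, ow = im2col(xp, self.k, self.stride)
        y = cols @ self.params["W"] + self.params["b"]
        if training:
            self._cache = (cols, xp.shape, x.shape)
        return y.reshape(x.shape[0], oh, ow, self.c_out)

    def _forward_s1(self, x, training):
        n, h, w, _ = x.shape
        p, k = self.pad, self.k
        hp, wp = h + 2 * p, w + 2 * p
        xp = _pad_hw(x, p)
        xf = xp.reshape(n * hp * wp, self.c_in)
        rows = n * hp * wp
        yf = np.empty((rows, self.c_out), dtype=np.float32)
        taps = self._taps()
        first = True
        for ti in range(k):
            for tj in range(k):
                off = (ti - p) * wp + (tj - p)
                lo, hi = max(0, -off), rows - max(0, off)
                _gemm_acc(yf[lo:hi], xf[lo + off : hi + off], taps[ti * k + tj],
                          beta=0.0 if first else 1.0)
                first = False
        y = yf.reshape(n, hp, wp, self.c_out)[:, p : p + h, p : p + w, :]
        y = y + self.params["b"]
        if training:
            self._cache = (xf, (n, hp, wp), x.shape)
        return y

    def backward(self, dy, need_dx=True):
        if self.stride == 1:
            return self._backward_s1(dy, need_dx)
        cols, xp_shape, x_shape = self._cache
        self._cache = None
        n, oh, ow, _ = dy.shape
        dyf = dy.reshape(n * oh * ow, self.c_out)
        self.grads["W"] = cols.T @ dyf
        self.grads["b"] = dyf.sum(axis=0)
        if not need_dx:
            return None
        dcols = dyf @ self.params["W"].T
        dxp = col2im(dcols, xp_shape, self.k, self.stride)
        p = self.pad
        return dxp[:, p : p + x_shape[1], p : p + x_shape[2], :]

    def _backward_s1(self, dy, need_dx=True):
        xf, (n, hp, wp), x_shape = self._cache
        self._cache = None
        p, k = self.pad, self.k
        h, w = x_shape[1], x_shape[2]
        rows = n * hp * wp
        # place dy in a zero-padded grid so border garbage never couples in
        dyp = np.zeros((n, hp, wp, self.c_out), dtype=np.float32)
        dyp[:, p : p + h, p : p + w, :] = dy
        dyf = dyp.reshape(rows, self.c_out)
        taps = self._taps()
        dW = np.empty_like(taps)
        dxf = np.zeros((rows, self.c_in), dtype=np.float32) if need_dx else None
        for ti in range(k):
            for tj in range(k):
                off = (ti - p) * wp + (tj - p)
                lo, hi = max(0, -off), rows - max(0, off)
                src = xf[lo + off : hi + off]
                dst = dyf[lo:hi]
                # dW_tap = src.T @ dst, with both transposes F-contiguous views
                dW[ti * k + tj] = sgemm(1.0, src.T, dst.T, trans_b=1)
                if need_dx:
                    _gemm_acc(dxf[lo + off : hi + off], dst, taps[ti * k + tj].T)
        self.grads["W"] = dW.reshape(self.params["W"].shape)
        self.grads["b"] = dy.sum(axis=(0, 1, 2))
        if not need_dx:
            return None
        return dxf.reshape(n, hp, wp, self.c_in)[:, p : p + h, p : p + w, :]


class ConvTranspose2d(Layer):
    """Stride-2 transposed k x k convolution (exact adjoint of Conv2d).

    Maps (N, H, W, c_in) -> (N, 2H, 2W, c_out); the forward pass is the
    data-gradient of a stride-2 "same" convolution, which guarantees the
    output shape matches the encoder level it is concatenated with.
    """

    kind = "conv"

    def __init__(self, name, c_in, c_out, k=3, rng=None):
        super().__init__(name)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, 2
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (k * k * c_in))
        # stored like the matching stride-2 Conv2d matrix for the reverse
        # map: rows index (c_out, tap_i, tap_j), columns index c_in.
        self.params["W"] = rng.normal(0.0, std, size=(c_out * k * k, c_in)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    def forward(self, x, training):
        n, h, w, _ = x.shape
        oh, ow = 2 * h, 2 * w
        p = self.k // 2
        cols = x.reshape(n * h * w, self.c_in) @ self.params["W"].T
        yp = col2im(cols, (n, oh + 2 * p, ow + 2 * p, self.c_out), self.k, self.stride)
        y = yp[:, p : p + oh, p : p + ow, :] + self.params["b"]
        if training:
            self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        self._cache = None
        n, h, w, _ = x.shape
        p = self.k // 2
        dyp = _pad_hw(dy, p)
        cols, _, _ = im2col(dyp, self.k, self.stride)
        xf = x.reshape(n * h * w, self.c_in)
        self.grads["W"] = cols.T @ xf
        self.grads["b"] = dy.sum(axis=(0, 1, 2))
        return (cols @ self.params["W"]).reshape(x.shape)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Training mode uses batch moments and updates the running buffers;
    frozen layers (``trainable=False``) always use the running buffers
    and leave them untouched, so a frozen layer is bit-stable.
    """

    kind = "bn"

    def __init__(self, name, c, eps=1e-5, momentum=0.1):
        super().__init__(name)
        self.c, self.eps, self.momentum = c, eps, momentum
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def forward(self, x, training):
        if training and self.trainable:
            mean, var = bn_stats(x)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var.astype(np.float64) + self.eps)).astype(np.float32)
        mean = np.asarray(mean, dtype=np.float32)
        # y = gamma * (x - mean) * inv + beta, folded to one multiply-add
        scale = self.params["gamma"] * inv
        shift = self.params["beta"] - mean * scale
        y = bn_forward(x, scale, shift)
        if training:
            self._cache = (x, mean, inv, bool(self.trainable))
        return y

    def backward(self, dy):
        x, mean, inv, used_batch_stats = self._cache
        self._cache = None
        sum_dy, sum_dyx, dx = bn_backward(
            dy, x, mean, inv, self.params["gamma"], batch_mode=used_batch_stats
        )
        self.grads["gamma"] = sum_dyx.astype(np.float32)
        self.grads["beta"] = sum_dy.astype(np.float32)
        return dx


class ReLU(Layer):
    kind = "activation"

    def __init__(self, name):
        super().__init__(name)
        self._mask = None

    def forward(self, x, training):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0, out=x)  # conv/BN output is never reused upstream

    def backward(self, dy):
        mask = self._mask
        self._mask = None
        dy *= mask
        return dy


class Sigmoid(Layer):
    kind = "activation"

    def __init__(self, name):
        super().__init__(name)
        self._y = None

    def forward(self, x, training):
        y = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._y = y
        return y.astype(np.float32)

    def backward(self, dy):
        y = self._y
        self._y = None
        return (dy * y * (1.0 - y)).astype(np.float32)
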