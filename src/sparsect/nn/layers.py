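"""Minimal NumPy layer library for the two post-processing CNNs.

Tensors are ``float32`` in NHWC layout ``(batch, height, width, channels)``.
Every layer implements ``forward`` (caching what its ``backward`` needs) and
``backward`` (returning the gradient w.r.t. its input and accumulating
parameter gradients).  Convolutions are stride-1 with zero "same" padding and
are evaluated as im2col + GEMM, which is where essentially all the training
time goes; im2col buffers are built per sample to bound memory.
"""

from __future__ import annotations

import numpy as np

from . import fastconv
from .fastconv import bn_apply, bn_backward, bn_stats, col2im_into, im2col_into

fastconv.tune_allocator()

# Cap on a convolution's transient column buffer; batches are chunked so the
# buffer stays resident and hot instead of being reallocated per call.
_COL_BUDGET_BYTES = 192 * 1024 * 1024

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Tanh",
    "Identity",
    "MaxPool2x2",
    "AvgPool2x2",
    "UpsampleNearest2x",
    "Sequential",
]


class Param:
    """A named trainable array with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Module):
    """Stride-1 2D convolution with zero 'same' padding.

    Evaluated as im2col (numba gather over the whole batch) + one GEMM.
    The column matrix is rebuilt in ``backward`` rather than cached: for the
    wide layers it is an order of magnitude larger than the activations.
    ``first_layer=True`` skips the input-gradient computation (the image is
    not trainable), which saves one GEMM per backward pass.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator | None = None, name: str = "conv",
                 first_layer: bool = False):
        if kernel % 2 != 1:
            raise ValueError("odd kernel sizes only (same padding)")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.first_layer = first_layer
        fan_in = kernel * kernel * in_channels
        if rng is None:
            rng = np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(fan_in, out_channels)).astype(np.float32)
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(out_channels, np.float32))
        self._x = None
        self._colbuf = None
        self._col_valid = False

    # -- weight views -----------------------------------------------------
    @property
    def kernel4d(self) -> np.ndarray:
        """Weights as (k, k, cin, cout)."""
        return self.weight.value.reshape(self.k, self.k, self.cin, self.cout)

    def _chunk_setup(self, H: int, W: int) -> int:
        """Images per im2col chunk and (re)size the persistent buffer."""
        kkc = self.k * self.k * self.cin
        per_img = H * W * kkc * 4
        m = max(1, _COL_BUDGET_BYTES // max(per_img, 1))
        rows = m * H * W
        if self._colbuf is None or self._colbuf.shape != (rows, kkc):
            self._colbuf = np.empty((rows, kkc), np.float32)
        return m

    def forward(self, x, training=True):
        N, H, W, C = x.shape
        assert C == self.cin, (C, self.cin)
        self._x = x
        m = self._chunk_setup(H, W)
        out = np.empty((N * H * W, self.cout), np.float32)
        Wm = self.weight.value
        for n0 in range(0, N, m):
            n1 = min(n0 + m, N)
            rows = (n1 - n0) * H * W
            col = self._colbuf[:rows]
            im2col_into(x[n0:n1], self.k, col)
            np.matmul(col, Wm, out=out[n0 * H * W:n1 * H * W])
        # single-chunk batches leave the column matrix reusable in backward
        self._col_valid = m >= N
        out += self.bias.value
        return out.reshape(N, H, W, self.cout)

    def backward(self, dy):
        x = self._x
        N, H, W, _ = x.shape
        g = dy.reshape(N * H * W, self.cout)
        self.bias.grad += g.sum(axis=0)
        m = self._chunk_setup(H, W)
        Wm = self.weight.value
        dx = None if self.first_layer else np.empty_like(x)
        for n0 in range(0, N, m):
            n1 = min(n0 + m, N)
            rows = (n1 - n0) * H * W
            col = self._colbuf[:rows]
            gc = g[n0 * H * W:n1 * H * W]
            if not self._col_valid:
                im2col_into(x[n0:n1], self.k, col)
            self.weight.grad += col.T @ gc
            if dx is None:
                continue
            np.matmul(gc, Wm.T, out=col)   # reuse buffer: col becomes dcol
            self._col_valid = False
            col2im_into(col, self.k, dx[n0:n1])
        self._col_valid = False
        return dx

    def params(self):
        return [self.weight, self.bias]


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, with affine terms."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.eps, self.momentum = eps, momentum
        self.name = name
        self.track_running = True    # cleared during stat-free inference
        self.gamma = Param(f"{name}.gamma", np.ones(channels, np.float32))
        self.beta = Param(f"{name}.beta", np.zeros(channels, np.float32))
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self._cache = None

    def forward(self, x, training=True):
        if training:
            mu, var = bn_stats(x)
            if self.track_running:
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(np.float32)
                self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = np.empty_like(x)
        y = np.empty_like(x)
        bn_apply(x, mu, invstd, self.gamma.value, self.beta.value, xhat, y)
        if training:
            self._cache = (xhat, invstd)
        return y

    def backward(self, dy):
        xhat, invstd = self._cache
        dx = np.empty_like(dy)
        dgamma, dbeta = bn_backward(dy, xhat, invstd, self.gamma.value, dx)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        return dx

    def params(self):
        return [self.gamma, self.beta]


class ReLU(Module):
    def forward(self, x, training=True):
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0))

    def backward(self, dy):
        return np.where(self._mask, dy, np.float32(0))


class Tanh(Module):
    def forward(self, x, training=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y * self._y)


class Identity(Module):
    def forward(self, x, training=True):
        return x

    def backward(self, dy):
        return dy


class MaxPool2x2(Module):
    """2x2 max pooling with stride 2 (ties resolved to the first element)."""

    def forward(self, x, training=True):
        N, H, W, C = x.shape
        r = x.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
        r = r.reshape(N, H // 2, W // 2, C, 4)
        self._idx = r.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        N, H, W, C = self._in_shape
        dr = np.zeros((N, H // 2, W // 2, C, 4), np.float32)
        np.put_along_axis(dr, self._idx[..., None], dy[..., None], axis=-1)
        dr = dr.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dr.reshape(N, H, W, C)


class AvgPool2x2(Module):
    """2x2 average pooling; used by the receptive-field probe, where the
    max-pool's argmax would under-report the dependence support."""

    def forward(self, x, training=True):
        N, H, W, C = x.shape
        self._in_shape = x.shape
        return x.reshape(N, H // 2, 2, W // 2, 2, C).mean(axis=(2, 4))

    def backward(self, dy):
        N, H, W, C = self._in_shape
        return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) * np.float32(0.25)


class UpsampleNearest2x(Module):
    def forward(self, x, training=True):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy):
        N, H, W, C = dy.shape
        return dy.reshape(N, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x, training=True):
        for m in self.modules:
            x = m.forward(x, training=training)
        return x

    def backward(self, dy):
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy

    def params(self):
        out = []
        for m in self.modules:
            out.extend(m.params())
        return out
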