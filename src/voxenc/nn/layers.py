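"""Minimal CPU neural-network layers with explicit forward/backward passes.

Each layer caches whatever it needs from the most recent ``forward`` call and
consumes that cache in ``backward``; a forward must therefore always be paired
with at most one backward before the next forward.  Parameters are plain
:class:`Param` objects; gradient steps are applied by the optimizer in
``voxenc.nn.optim``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Conv2d", "BatchNorm2d", "Dropout", "ReLU", "MaxPool2d",
]


class Param:
    """A trainable array with an accumulated gradient and a freeze flag."""

    __slots__ = ("v", "g", "frozen")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float64)
        self.g = np.zeros_like(self.v)
        self.frozen = False

    def zero_grad(self) -> None:
        self.g[...] = 0.0


class Layer:
    train_mode_uses_rng = False

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution (cross-correlation) via an im2col offset loop.

    ``pad=None`` means "same" padding for the given kernel, so with stride 1
    the spatial resolution is preserved.
    """

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        self.cin, self.cout, self.k, self.stride = cin, cout, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        fan_in = cin * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kernel, kernel))
        self.w = Param(w)
        self.b = Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        b, c, _, _ = xp.shape
        k, s = self.k, self.stride
        cols = np.empty((b, c, k, k, ho, wo), dtype=xp.dtype)
        for di in range(k):
            for dj in range(k):
                cols[:, :, di, dj] = xp[:, :, di:di + s * ho:s, dj:dj + s * wo:s]
        return cols

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        ho, wo = self.out_shape(h, w)
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = self._im2col(xp, ho, wo).reshape(b, c * self.k * self.k, ho * wo)
        wm = self.w.v.reshape(self.cout, -1)
        y = np.einsum("ok,bkp->bop", wm, cols, optimize=True)
        y += self.b.v[None, :, None]
        self._cache = (cols, xp.shape, (ho, wo))
        return y.reshape(b, self.cout, ho, wo)

    def backward(self, dy):
        cols, xp_shape, (ho, wo) = self._cache
        b = dy.shape[0]
        dyf = dy.reshape(b, self.cout, ho * wo)
        self.w.g += np.einsum("bop,bkp->ok", dyf, cols,
                              optimize=True).reshape(self.w.v.shape)
        self.b.g += dyf.sum(axis=(0, 2))
        wm = self.w.v.reshape(self.cout, -1)
        dcols = np.einsum("ok,bop->bkp", wm, dyf, optimize=True)
        dcols = dcols.reshape(b, self.cin, self.k, self.k, ho, wo)
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        s = self.stride
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di:di + s * ho:s, dj:dj + s * wo:s] += dcols[:, :, di, dj]
        p = self.pad
        return dxp[:, :, p:-p or None, p:-p or None] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.v[None, :, None, None] * xhat + self.beta.v[None, :, None, None]

    def backward(self, dy):
        xhat, inv, train, shape = self._cache
        self.gamma.g += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.g += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.v[None, :, None, None]
        if not train:
            return dxhat * inv[None, :, None, None]
        n = shape[0] * shape[2] * shape[3]
        sum_d = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dx = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / n) * (n * dxhat - sum_d - xhat * sum_dx)


class Dropout(Layer):
    train_mode_uses_rng = True

    def __init__(self, rate: float = 0.25):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout.rng must be set before training")
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (spatial dimensions must be even)."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d requires even spatial dims, got {h}x{w}")
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(b, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, shape = self._cache
        b, c, h, w = shape
        dxr = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(b, c, h, w)
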