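"""Minimal NumPy neural-network layers for 2D encoder-decoder segmentation.

All layers operate on ``float32`` arrays in NHWC layout (batch, height,
width, channels). Each layer implements ``forward(x, train=False)`` and
``backward(dy)``; trainable arrays are :class:`Param` objects so an
optimizer can iterate over ``layer.params()``.

The max-pooling operator returns the argmax position of every pooling
window (its window-local flat coordinate, row-major); ``MaxUnpool2D``
scatters pooled values back to exactly those positions. Ties are broken
by the first occurrence in row-major order — this is the contract that
makes stored indices reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "ConvTranspose2x2",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "MaxPool2D",
    "MaxUnpool2D",
    "NearestUpsample2x",
    "maxpool_with_indices",
    "max_unpool",
]


class Param:
    """A trainable array together with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def glorot_uniform(shape, fan_in, fan_out, rng) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D(Layer):
    """Same-padded stride-1 convolution (cross-correlation), square kernel.

    Implemented as a sum of shifted matrix products — one (NHW, C) @ (C, F)
    product per kernel offset — which keeps peak memory at one padded copy
    of the input instead of a full im2col buffer.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = kernel * kernel * in_ch
        fan_out = kernel * kernel * out_ch
        self.W = Param(glorot_uniform((kernel, kernel, in_ch, out_ch), fan_in, fan_out, rng))
        self.b = Param(np.zeros(out_ch, dtype=np.float32))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def n_params(self) -> int:
        return self.out_ch * (self.k * self.k * self.in_ch + 1)

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        y = np.empty((n, h, w, self.out_ch), dtype=xp.dtype)
        y[:] = self.b.value
        flat = y.reshape(-1, self.out_ch)
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, i : i + h, j : j + w, :].reshape(-1, c)
                flat += xs @ self.W.value[i, j]
        return y

    def backward(self, dy):
        xp = self._xp
        n, hp, wp, c = xp.shape
        h, w = dy.shape[1], dy.shape[2]
        dyf = dy.reshape(-1, self.out_ch)
        self.b.grad += dyf.sum(axis=0)
        dxp = np.zeros_like(xp)
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, i : i + h, j : j + w, :].reshape(-1, c)
                self.W.grad[i, j] += xs.T @ dyf
                dxp[:, i : i + h, j : j + w, :] += (dyf @ self.W.value[i, j].T).reshape(n, h, w, c)
        p = self.k // 2
        if p == 0:
            return dxp
        return dxp[:, p : hp - p, p : wp - p, :]


class ConvTranspose2x2(Layer):
    """Stride-2 2x2 transposed convolution: doubles the spatial resolution.

    Each input pixel emits an independent 2x2 output block, so the operator
    reduces to a single matrix product followed by a block rearrangement.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = in_ch
        fan_out = 4 * out_ch
        self.W = Param(glorot_uniform((2, 2, in_ch, out_ch), fan_in, fan_out, rng))
        self.b = Param(np.zeros(out_ch, dtype=np.float32))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def n_params(self) -> int:
        return self.out_ch * (4 * self.in_ch + 1)

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        wm = self.W.value.transpose(2, 0, 1, 3).reshape(c, 4 * self.out_ch)
        self._x = x
        y = (x.reshape(-1, c) @ wm).reshape(n, h, w, 2, 2, self.out_ch)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, self.out_ch)
        return y + self.b.value

    def backward(self, dy):
        x = self._x
        n, h, w, c = x.shape
        self.b.grad += dy.sum(axis=(0, 1, 2))
        dblk = dy.reshape(n, h, 2, w, 2, self.out_ch).transpose(0, 1, 3, 2, 4, 5)
        dblk = dblk.reshape(-1, 4 * self.out_ch)
        wm = self.W.value.transpose(2, 0, 1, 3).reshape(c, 4 * self.out_ch)
        dwm = x.reshape(-1, c).T @ dblk
        self.W.grad += dwm.reshape(c, 2, 2, self.out_ch).transpose(1, 2, 0, 3)
        return (dblk @ wm.T).reshape(n, h, w, c)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        # split by sign for numerical stability
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._y = out
        return out

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity when ``train=False`` or rate == 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


def _windows(x: np.ndarray, w: int):
    """(N,H,W,C) -> (N,H/w,W/w,C,w*w) window view, row-major within window."""
    n, h, wd, c = x.shape
    if h % w or wd % w:
        raise ValueError(f"spatial dims ({h},{wd}) not divisible by window {w}")
    v = x.reshape(n, h // w, w, wd // w, w, c)
    return v.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // w, wd // w, c, w * w)


def maxpool_with_indices(features: np.ndarray, window: int = 2, stride: int = 2):
    """Non-overlapping max pooling that records each window's argmax.

    Returns ``(pooled, indices)`` where ``indices[..]`` is the window-local
    flat coordinate (row-major, in ``0..window**2 - 1``) of the maximum.
    Ties resolve to the first occurrence in row-major order. Accepts a 2D
    ``(H, W)`` grid or a 4D NHWC batch.
    """
    if window != stride:
        raise ValueError("only window == stride pooling is supported")
    x = np.asarray(features)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None, :, :, None]
    win = _windows(x, window)
    idx = np.argmax(win, axis=-1)
    pooled = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    if squeeze:
        return pooled[0, :, :, 0], idx[0, :, :, 0]
    return pooled, idx


def max_unpool(pooled: np.ndarray, indices: np.ndarray, output_size, window: int = 2):
    """Scatter pooled values back to their argmax positions; zeros elsewhere."""
    p = np.asarray(pooled)
    idx = np.asarray(indices)
    squeeze = p.ndim == 2
    if squeeze:
        p = p[None, :, :, None]
        idx = idx[None, :, :, None]
    if p.shape != idx.shape:
        raise ValueError(f"pooled shape {p.shape} != indices shape {idx.shape}")
    oh, ow = output_size
    n, hp, wp, c = p.shape
    if oh != hp * window or ow != wp * window:
        raise ValueError(
            f"output size {output_size} inconsistent with pooled {hp}x{wp} and window {window}"
        )
    if idx.min() < 0 or idx.max() >= window * window:
        raise ValueError("indices outside their pooling windows")
    out = np.zeros((n, hp, wp, c, window * window), dtype=p.dtype)
    np.put_along_axis(out, idx[..., None], p[..., None], axis=-1)
    out = out.reshape(n, hp, wp, c, window, window).transpose(0, 1, 4, 2, 5, 3)
    out = out.reshape(n, oh, ow, c)
    if squeeze:
        return out[0, :, :, 0]
    return out


class MaxPool2D(Layer):
    """2x2 stride-2 max pooling; exposes ``.indices`` for a paired unpool."""

    def __init__(self, window: int = 2):
        self.window = window
        self.indices: np.ndarray | None = None
        self._in_shape = None

    def forward(self, x, train=False):
        self._in_shape = x.shape
        pooled, self.indices = maxpool_with_indices(x, self.window, self.window)
        return pooled

    def backward(self, dy):
        n, h, w, c = self._in_shape
        return max_unpool(dy, self.indices, (h, w), self.window)


class MaxUnpool2D(Layer):
    """Upsampling by index scatter, paired with a specific MaxPool2D."""

    def __init__(self, source: MaxPool2D):
        self.source = source

    def forward(self, x, train=False):
        n, h, w, c = self.source._in_shape
        if x.shape != self.source.indices.shape:
            raise ValueError(
                f"feature shape {x.shape} does not match pooling indices "
                f"{self.source.indices.shape}"
            )
        return max_unpool(x, self.source.indices, (h, w), self.source.window)

    def backward(self, dy):
        win = _windows(dy, self.source.window)
        return np.take_along_axis(win, self.source.indices[..., None], axis=-1)[..., 0]


class NearestUpsample2x(Layer):
    """Non-learned 2x nearest-neighbour upsampling."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
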