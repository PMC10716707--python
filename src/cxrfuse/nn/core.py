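"""Minimal CPU neural-network layer library (numpy, manual backprop).

Layers follow a ``forward(x, train=...)`` / ``backward(dy)`` contract and
expose their parameters as named :class:`Param` objects so an optimizer
can update them in place.  The data layout for images is NCHW.  All
arithmetic is float64; inference is deterministic (dropout is identity
outside training).
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, expit


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base class: stateless layers may skip everything but forward/backward."""

    def params(self) -> list[tuple[str, Param]]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for _, p in self.params())


class Dense(Layer):
    """Affine map on the last axis; arbitrary leading dimensions."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_dim + out_dim))
        self.w = Param(rng.normal(0.0, scale, size=(in_dim, out_dim)))
        self.b = Param(np.zeros(out_dim))
        self._x: np.ndarray | None = None

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.w.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.w.value.T


class Conv2d(Layer):
    """2-D convolution with 'same' zero padding (odd kernels) and stride 1,
    computed as a shift-and-add over kernel offsets (no im2col buffer)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: str = "same"):
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        if padding == "same" and kernel % 2 == 0:
            raise ValueError("'same' padding requires an odd kernel")
        fan_in = in_ch * kernel * kernel
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(out_ch, in_ch, kernel, kernel)))
        self.b = Param(np.zeros(out_ch))
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self._xp: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def _pad(self) -> int:
        return (self.kernel - 1) // 2 if self.padding == "same" else 0

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self._pad()
        self._in_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp = xp
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        out = np.empty((n, self.w.value.shape[0], ho, wo))
        out[:] = self.b.value[None, :, None, None]
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                out += np.tensordot(self.w.value[:, :, i, j], patch,
                                    axes=(1, 1)).transpose(1, 0, 2, 3)
        return out

    def backward(self, dy):
        xp = self._xp
        n, c, hp, wp = xp.shape
        k, s = self.kernel, self.stride
        ho, wo = dy.shape[2], dy.shape[3]
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                self.w.grad[:, :, i, j] += np.tensordot(
                    dy, patch, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += np.tensordot(
                    self.w.value[:, :, i, j], dy,
                    axes=(0, 1)).transpose(1, 0, 2, 3)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        p = self._pad()
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class MaxPool2d(Layer):
    """Non-overlapping max pooling (kernel == stride); trailing rows/cols
    that do not fill a window are dropped."""

    def __init__(self, kernel: int):
        self.kernel = kernel
        self._idx: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x, train=False):
        k = self.kernel
        n, c, h, w = x.shape
        ho, wo = h // k, w // k
        xt = x[:, :, :ho * k, :wo * k]
        self._shape = (x.shape, xt.shape)
        win = xt.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, ho, wo, k * k)
        self._idx = win.argmax(axis=-1)
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        k = self.kernel
        full_shape, trimmed = self._shape
        n, c, ht, wt = trimmed
        ho, wo = ht // k, wt // k
        dwin = np.zeros((n, c, ho, wo, k * k))
        np.put_along_axis(dwin, self._idx[..., None], dy[..., None], axis=-1)
        dxt = dwin.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
        dxt = dxt.reshape(n, c, ht, wt)
        dx = np.zeros(full_shape)
        dx[:, :, :ht, :wt] = dxt
        return dx


class GlobalMaxPool2d(Layer):
    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        self._shape = x.shape
        flat = x.reshape(n, c, h * w)
        self._idx = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h * w))
        np.put_along_axis(dflat, self._idx[..., None], dy[..., None], axis=-1)
        return dflat.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class GELU(Layer):
    """Exact Gaussian-error-linear unit: x * Phi(x)."""

    def forward(self, x, train=False):
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        return x * self._cdf

    def backward(self, dy):
        x = self._x
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return dy * (self._cdf + x * pdf)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = expit(x)
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class LayerNorm(Layer):
    """Normalization over the last axis with learned gain and bias."""

    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.eps = eps

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x, train=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        d = xhat.shape[-1]
        self.gamma.grad += (dy * xhat).reshape(-1, d).sum(axis=0)
        self.beta.grad += dy.reshape(-1, d).sum(axis=0)
        dxhat = dy * self.gamma.value
        return inv * (dxhat
                      - dxhat.mean(axis=-1, keepdims=True)
                      - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, p in layer.params():
                out.append((f"{i}.{type(layer).__name__.lower()}.{name}", p))
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def zero_grads(params: list[tuple[str, Param]]) -> None:
    for _, p in params:
        p.grad[...] = 0.0
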