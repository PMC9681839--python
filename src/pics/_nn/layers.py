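"""Layer primitives with explicit forward/backward passes.

Conventions: inputs are float32 NCHW arrays; ``forward(x, train)`` caches
whatever ``backward(gy)`` needs; ``backward`` returns the gradient w.r.t. the
layer input and accumulates parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "Tanh",
    "Dropout",
    "MaxPool2d",
    "Upsample2x",
    "Sequential",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # -- weight snapshots -------------------------------------------------
    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N*Ho*Wo, C*k*k) patch matrix (copies)."""
    n, c, hp, wp = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return view.transpose(0, 4, 5, 1, 2, 3).reshape(n * ho * wo, c * k * k)


class Conv2d(Layer):
    """k x k convolution, 'same'-style symmetric zero padding by default."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        bias: bool = True,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        fan_in = in_ch * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.w = Param(w)
        self.b = Param(np.zeros(out_ch)) if bias else None
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else np.ascontiguousarray(x)
        n, _, hp, wp = xp.shape
        ho = (hp - self.k) // self.stride + 1
        wo = (wp - self.k) // self.stride + 1
        cols = _im2col(xp, self.k, self.stride)
        y = cols @ self.w.value.T
        if self.b is not None:
            y += self.b.value
        if train:
            self._cache = (cols, xp.shape, (n, ho, wo))
        return y.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (n, ho, wo) = self._cache
        gy2 = gy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_ch)
        self.w.grad += gy2.T @ cols
        if self.b is not None:
            self.b.grad += gy2.sum(axis=0)
        gcols = gy2 @ self.w.value  # (N*Ho*Wo, C*k*k)
        gxp = np.zeros(xp_shape, dtype=np.float32)
        g6 = gcols.reshape(n, ho, wo, self.in_ch, self.k, self.k).transpose(0, 3, 4, 5, 1, 2)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                gxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += g6[:, :, i, j]
        p = self.pad
        return gxp[:, :, p : gxp.shape[2] - p, p : gxp.shape[3] - p] if p else gxp


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    # running stats are part of the snapshot even though they get no gradient
    def state(self) -> list[np.ndarray]:
        return super().state() + [self.running_mean.copy(), self.running_var.copy()]

    def load_state(self, state: list[np.ndarray]) -> None:
        super().load_state(state[:2])
        self.running_mean[...] = state[2]
        self.running_var[...] = state[3]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = self.gamma.value[:, None, None]
        gxhat = gy * g
        gx = (
            gxhat
            - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        ) * inv_std[:, None, None]
        return gx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=False):
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy):
        return gy * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.where(x > 0, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if train:
            self._y = y
        return y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class Tanh(Layer):
    def forward(self, x, train=False):
        y = np.tanh(x)
        if train:
            self._y = y
        return y

    def backward(self, gy):
        return gy * (1.0 - self._y * self._y)


class Dropout(Layer):
    """Inverted dropout; active only in training mode (the GAN's noise source)."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(np.float32)

    def backward(self, gy):
        return gy if self._mask is None else (gy * self._mask).astype(np.float32)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; input H, W must be even."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            self._mask = xr == y[:, :, :, None, :, None]
            self._shape = x.shape
        return y

    def backward(self, gy):
        n, c, h, w = self._shape
        g = self._mask * gy[:, :, :, None, :, None]
        # ties (equal maxima in a window) would double-route gradient; split it
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        return (g / counts).reshape(n, c, h, w).astype(np.float32)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train=False):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, gy):
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def state(self) -> list[np.ndarray]:
        return [a for layer in self.layers for a in layer.state()]

    def load_state(self, state: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            n = len(layer.state())
            layer.load_state(state[i : i + n])
            i += n

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy
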