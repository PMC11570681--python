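"""Minimal CPU neural-network layer library (numpy, manual backprop).

The reconstruction generator and discriminator are built from these
primitives: 3x3/strided convolutions via im2col, 2x transposed
convolutions, batch normalization, ReLU/LeakyReLU, 2x2 max pooling, and
an Adam optimizer.  Every layer caches what its backward pass needs, so
a composite network runs ``forward`` then ``backward`` in reverse order;
gradients accumulate into ``Param.grad`` until ``zero_grad`` is called.

Determinism: all weight initialization draws from an explicit
``numpy.random.Generator``, and the math is pure numpy, so a fixed seed
reproduces training bit-for-bit on CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "MaxPool2d",
    "Sequential",
    "Adam",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)


class Layer:
    """Base layer: subclasses implement forward/backward and list params."""

    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Trainable and buffer arrays for checkpointing (override to add buffers)."""
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with zero padding, via im2col."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride, self.padding = k, stride, padding
        fan_in = in_channels * k * k
        self.weight = Param(_he_init(rng, (out_channels, fan_in), fan_in))
        self.bias = Param(np.zeros(out_channels))
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        if train:
            self._cols = cols
            self._xshape = (n, c, h, w)
        y = cols @ self.weight.data.T + self.bias.data
        return y.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cols is not None, "forward(train=True) must precede backward"
        n, co, ho, wo = dy.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        c = self.in_channels
        _, _, h, w = self._xshape  # original (unpadded) spatial size
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, co)
        self.weight.grad += dyf.T @ self._cols
        self.bias.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.weight.data).reshape(n, ho, wo, c, k, k).transpose(
            0, 3, 1, 2, 4, 5
        )
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[..., i, j]
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ConvTranspose2d(Layer):
    """Stride-2, kernel-2 transposed convolution (exact 2x upsampling).

    With kernel == stride the output patches do not overlap, so the
    operation is a per-pixel linear map followed by a space-to-depth
    rearrangement — cheap in both directions.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        fan_in = in_channels
        self.weight = Param(_he_init(rng, (in_channels, out_channels, 2, 2), fan_in))
        self.bias = Param(np.zeros(out_channels))
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        n, c, h, w = x.shape
        t = np.tensordot(x, self.weight.data, axes=([1], [0]))  # n,h,w,co,2,2
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.out_channels, 2 * h, 2 * w)
        return y + self.bias.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        n, co, h2, w2 = dy.shape
        h, w = h2 // 2, w2 // 2
        dt = dy.reshape(n, co, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # n,h,w,co,2,2
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        self.weight.grad += np.tensordot(self._x, dt, axes=([0, 2, 3], [0, 1, 2]))
        dx = np.tensordot(dt, self.weight.data, axes=([3, 4, 5], [1, 2, 3]))
        self._x = None
        return dx.transpose(0, 3, 1, 2)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum, self.eps = momentum, eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache: tuple | None = None

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state_arrays(self) -> dict[str, np.ndarray]:
        d = super().state_arrays()
        d["running_mean"] = self.running_mean
        d["running_var"] = self.running_var
        return d

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv = self._cache
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        dxhat = dy * g
        mean_dxhat = dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        dx = inv[None, :, None, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        self._cache = None
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dx = dy * self._mask
        self._mask = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.where(x > 0, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dx = np.where(self._mask, dy, self.slope * dy)
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """2x2 max pooling; ties resolve to the first maximum (fixed order)."""

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        if train:
            self._idx = idx
            self._shape = (n, c, h, w)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._idx is not None and self._shape is not None
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, self._idx[..., None], dy[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return dx.reshape(n, c, h, w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def state_arrays(self) -> dict[str, np.ndarray]:
        d: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state_arrays().items():
                d[f"l{i}.{k}"] = v
        return d


class Adam:
    """Adam optimizer over a flat parameter list; ``lr`` is mutable."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
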