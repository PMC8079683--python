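"""Minimal seeded NumPy neural-network engine.

Implements the layer zoo needed by the three baseline architectures
(3x3/1x1/7x7 convolutions, batch normalization, ReLU, max/avg pooling,
global average pooling, dense layers, pre-activation residual blocks and
densely connected blocks) with explicit forward/backward passes and an
Adam optimizer.  All arrays are float64 NCHW; weight initialization is
He fan-in scaling driven by a caller-supplied Generator, so two builds
from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "Sigmoid",
    "MaxPool2",
    "AvgPool2",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "PreActIdentityBlock",
    "PreActProjectionBlock",
    "DenseUnit",
    "DenseBlock",
    "Transition",
    "Adam",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    """Base layer: forward caches what backward needs."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2D(Layer):
    """2-D convolution via im2col; 'same' padding, square kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3,
                 stride: int = 1, rng: np.random.Generator | None = None) -> None:
        if rng is None:
            rng = np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2
        fan_in = c_in * kernel * kernel
        self.w = Param(he_init(rng, (fan_in, c_out), fan_in), "conv.w")
        self.b = Param(np.zeros(c_out), "conv.b")
        self._idx_cache: dict[tuple, np.ndarray] = {}

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho, wo = self._out_hw(h, w)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                      # (n, c, ho, wo, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        out = cols @ self.w.value + self.b.value       # (n, ho*wo, c_out)
        self._cache = (cols, x.shape, xp.shape, (ho, wo))
        return out.transpose(0, 2, 1).reshape(n, self.c_out, ho, wo)

    def _col2im_idx(self, xp_shape: tuple, ho: int, wo: int) -> np.ndarray:
        key = (xp_shape, ho, wo)
        if key not in self._idx_cache:
            _, c, hp, wp = xp_shape
            k, s = self.k, self.stride
            l = np.arange(ho * wo)
            j = np.arange(c * k * k)
            cc = j // (k * k)
            dy = (j % (k * k)) // k
            dx = j % k
            rows = (l[:, None] // wo) * s + dy[None, :]
            colz = (l[:, None] % wo) * s + dx[None, :]
            self._idx_cache[key] = cc[None, :] * hp * wp + rows * wp + colz
        return self._idx_cache[key]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape, xp_shape, (ho, wo) = self._cache
        n, c, h, w = x_shape
        g = grad.reshape(n, self.c_out, ho * wo).transpose(0, 2, 1)  # (n, L, c_out)
        self.w.grad += np.einsum("nlj,nlo->jo", cols, g)
        self.b.grad += g.sum(axis=(0, 1))
        dcols = g @ self.w.value.T                                   # (n, L, c*k*k)
        _, _, hp, wp = xp_shape
        dxp = np.zeros((n, c * hp * wp))
        idx = self._col2im_idx(xp_shape, ho, wo)
        np.add.at(dxp, (np.arange(n)[:, None, None], idx[None, :, :]), dcols)
        dxp = dxp.reshape(n, c, hp, wp)
        p = self.pad
        if p:
            return dxp[:, :, p:hp - p, p:wp - p]
        return dxp


class BatchNorm2D(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.c = channels
        self.momentum, self.eps = momentum, eps
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._training = training
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not self._training:
            return g * inv_std[None, :, None, None]
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / n) * (n * g - sum_g - xhat * sum_gx)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; input H, W must be even."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4)
        self._arg = v.argmax(axis=-1)
        self._shape = x.shape
        return v.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(out, self._arg[..., None], grad[..., None], axis=-1)
        return out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class AvgPool2(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"AvgPool2 needs even spatial dims, got {h}x{w}")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        return g


class GlobalAvgPool(Layer):
    """(n, c, h, w) -> (n, c)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None) -> None:
        if rng is None:
            rng = np.random.default_rng(0)
        self.n_in, self.n_out = n_in, n_out
        self.w = Param(he_init(rng, (n_in, n_out), n_in), "dense.w")
        self.b = Param(np.zeros(n_out), "dense.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class _Chain(Layer):
    """Run sublayers in sequence (shared by the composite blocks)."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class PreActIdentityBlock(Layer):
    """Full pre-activation residual block: out = x + conv(relu(bn(conv(relu(bn(x))))))."""

    def __init__(self, width: int, rng: np.random.Generator) -> None:
        self.width = width
        self.branch = _Chain([
            BatchNorm2D(width), ReLU(), Conv2D(width, width, 3, 1, rng),
            BatchNorm2D(width), ReLU(), Conv2D(width, width, 3, 1, rng),
        ])

    def params(self) -> list[Param]:
        return self.branch.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x + self.branch.forward(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad + self.branch.backward(grad)


class PreActProjectionBlock(Layer):
    """Pre-activation residual block with a 1x1 projection shortcut.

    The shared BN-ReLU pre-activation feeds both the residual branch and
    the projection, which also carries the (possibly strided) width change.
    """

    def __init__(self, c_in: int, width: int, stride: int, rng: np.random.Generator) -> None:
        self.c_in, self.width, self.stride = c_in, width, stride
        self.pre = _Chain([BatchNorm2D(c_in), ReLU()])
        self.branch = _Chain([
            Conv2D(c_in, width, 3, stride, rng),
            BatchNorm2D(width), ReLU(), Conv2D(width, width, 3, 1, rng),
        ])
        self.proj = Conv2D(c_in, width, 1, stride, rng)

    def params(self) -> list[Param]:
        return self.pre.params() + self.branch.params() + self.proj.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        pre = self.pre.forward(x, training)
        return self.branch.forward(pre, training) + self.proj.forward(pre, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dpre = self.branch.backward(grad) + self.proj.backward(grad)
        return self.pre.backward(dpre)


class DenseUnit(Layer):
    """BN-ReLU-1x1 conv (bottleneck 4k) - BN-ReLU-3x3 conv (growth k)."""

    def __init__(self, c_in: int, growth: int, rng: np.random.Generator) -> None:
        self.c_in, self.growth = c_in, growth
        self.chain = _Chain([
            BatchNorm2D(c_in), ReLU(), Conv2D(c_in, 4 * growth, 1, 1, rng),
            BatchNorm2D(4 * growth), ReLU(), Conv2D(4 * growth, growth, 3, 1, rng),
        ])

    def params(self) -> list[Param]:
        return self.chain.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.chain.forward(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.chain.backward(grad)


class DenseBlock(Layer):
    """Densely connected block: unit i consumes concat(x, out_1..out_{i-1})."""

    def __init__(self, c_in: int, n_units: int, growth: int, rng: np.random.Generator) -> None:
        self.c_in, self.n_units, self.growth = c_in, n_units, growth
        self.units = [DenseUnit(c_in + i * growth, growth, rng) for i in range(n_units)]
        self.c_out = c_in + n_units * growth

    def params(self) -> list[Param]:
        return [p for u in self.units for p in u.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        feats = [x]
        for u in self.units:
            feats.append(u.forward(np.concatenate(feats, axis=1), training))
        self._widths = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # split the output gradient into per-feature slots, then run units
        # in reverse, scattering each unit's input gradient back onto the
        # slots of everything it consumed.
        bounds = np.cumsum([0] + self._widths)
        slots = [grad[:, bounds[i]:bounds[i + 1]].copy() for i in range(len(self._widths))]
        for i in reversed(range(self.n_units)):
            din = self.units[i].backward(slots[i + 1])
            b = np.cumsum([0] + self._widths[:i + 1])
            for j in range(i + 1):
                slots[j] += din[:, b[j]:b[j + 1]]
        return slots[0]


class Transition(Layer):
    """BN-ReLU-1x1 conv (compression) - 2x2 average pool."""

    def __init__(self, c_in: int, compression: float, rng: np.random.Generator) -> None:
        self.c_in = c_in
        self.c_out = int(np.floor(c_in * compression))
        self.chain = _Chain([
            BatchNorm2D(c_in), ReLU(), Conv2D(c_in, self.c_out, 1, 1, rng), AvgPool2(),
        ])

    def params(self) -> list[Param]:
        return self.chain.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.chain.forward(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.chain.backward(grad)


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
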