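"""Minimal CPU neural-network substrate: layers, manual backprop, Adam.

Everything operates on float32 NCHW arrays.  Each module implements
``forward(x, train)`` (caching what backward needs) and ``backward(gout)``
(returning the input gradient and accumulating parameter gradients).  There is
no computation graph; composite modules wire their children's backward passes
explicitly.  All initialisation draws from a caller-supplied
``numpy.random.Generator`` so builds and training runs are reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Module", "Conv2d", "BatchNorm2d", "ReLU", "Sigmoid",
    "MaxPool2d", "GlobalAvgPool2d", "Dense", "SEModule", "Adam",
    "im2col", "col2im",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    def params(self) -> list[Param]:
        out: list[Param] = []
        for attr in vars(self).values():
            if isinstance(attr, Param):
                out.append(attr)
            elif isinstance(attr, Module):
                out.extend(attr.params())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())


# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------

def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int,
           pad_value: float = 0.0) -> tuple[np.ndarray, tuple]:
    """(N, C, H, W) -> (N*Ho*Wo, C*kh*kw) patch matrix."""
    n, c, h, w = x.shape
    ho, wo = _out_size(h, kh, stride, pad), _out_size(w, kw, stride, pad)
    if pad:
        xp = np.full((n, c, h + 2 * pad, w + 2 * pad), pad_value, dtype=x.dtype)
        xp[:, :, pad:pad + h, pad:pad + w] = x
    else:
        xp = x
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                     # (N, C, Ho, Wo, kh, kw)
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(col), (n, c, h, w, ho, wo)


def col2im(dcol: np.ndarray, shape: tuple, kh: int, kw: int,
           stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back to (N, C, H, W)."""
    n, c, h, w, ho, wo = shape
    d = dcol.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += d[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp


# ---------------------------------------------------------------------------
# primitive layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    """2-D cross-correlation (the CNN convention for "convolution"); no bias
    since batch norm follows everywhere it is used."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0,
                 rng: np.random.Generator | None = None,
                 weight: np.ndarray | None = None):
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.padding = kernel, stride, padding
        if weight is not None:
            w = np.asarray(weight, dtype=np.float32)
            if w.shape != (out_channels, in_channels, kernel, kernel):
                raise ValueError(f"weight shape {w.shape} mismatches layer spec")
        else:
            rng = rng or np.random.default_rng()
            fan_in = in_channels * kernel * kernel
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(out_channels, in_channels, kernel, kernel))
        self.weight = Param(w)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        col, shape = im2col(x, self.kernel, self.kernel, self.stride, self.padding)
        self._col, self._shape = col, shape
        wmat = self.weight.value.reshape(self.out_channels, -1)
        out = col @ wmat.T
        n, _, _, _, ho, wo = shape
        return out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, co, ho, wo = gout.shape
        g2 = gout.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        self.weight.grad += (g2.T @ self._col).reshape(self.weight.value.shape)
        dcol = g2 @ self.weight.value.reshape(co, -1)
        return col2im(dcol, self._shape, self.kernel, self.kernel,
                      self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels, self.momentum, self.eps = channels, momentum, eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._xhat, self._inv, self._m = xhat, inv, x.shape[0] * x.shape[2] * x.shape[3]
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._xhat, self._inv, self._m
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        gxhat = gout * self.gamma.value[None, :, None, None]
        sum_g = gxhat.sum(axis=(0, 2, 3))
        sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3))
        return (inv[None, :, None, None] / m) * (
            m * gxhat
            - sum_g[None, :, None, None]
            - xhat * sum_gx[None, :, None, None]
        )


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class Sigmoid(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._y * (1.0 - self._y)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k = self.kernel
        col, shape = im2col(x, k, k, self.stride, self.padding,
                            pad_value=-np.inf)
        n, c, h, w, ho, wo = shape
        col = col.reshape(n * ho * wo, c, k * k)
        self._arg = col.argmax(axis=2)
        self._shape = shape
        out = np.take_along_axis(col, self._arg[:, :, None], axis=2)[:, :, 0]
        return out.reshape(n, ho, wo, c).transpose(0, 3, 1, 2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w, ho, wo = self._shape
        k = self.kernel
        g2 = gout.transpose(0, 2, 3, 1).reshape(n * ho * wo, c)
        dcol = np.zeros((n * ho * wo, c, k * k), dtype=gout.dtype)
        np.put_along_axis(dcol, self._arg[:, :, None], g2[:, :, None], axis=2)
        return col2im(dcol.reshape(n * ho * wo, c * k * k), self._shape,
                      k, k, self.stride, self.padding)


class GlobalAvgPool2d(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None] / self._hw,
                               self._shape).astype(gout.dtype).copy()


class Dense(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None,
                 weight: np.ndarray | None = None,
                 bias: np.ndarray | None = None):
        rng = rng or np.random.default_rng()
        if weight is None:
            weight = rng.normal(0.0, np.sqrt(2.0 / in_features),
                                size=(in_features, out_features))
        self.weight = Param(np.asarray(weight))
        self.bias = Param(np.zeros(out_features) if bias is None else np.asarray(bias))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ gout
        self.bias.grad += gout.sum(axis=0)
        return gout @ self.weight.value.T


class SEModule(Module):
    """Squeeze-and-excitation: global average (squeeze), two-layer bottleneck
    with sigmoid output (excitation), channel-wise rescaling.

    ``pinned`` forces all excitation weights to 1, turning the block into an
    identity rescaling (the plain-ResNet ablation switch).
    """

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator | None = None):
        if channels % reduction != 0:
            raise ValueError(
                f"reduction {reduction} must divide channel count {channels}"
            )
        hidden = channels // reduction
        self.fc1 = Dense(channels, hidden, rng=rng)
        self.relu = ReLU()
        self.fc2 = Dense(hidden, channels, rng=rng)
        self.sigmoid = Sigmoid()
        self.pinned = False

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        self._hw = x.shape[2] * x.shape[3]
        z = x.mean(axis=(2, 3))                               # squeeze
        s = self.sigmoid.forward(
            self.fc2.forward(self.relu.forward(self.fc1.forward(z, train), train), train),
            train,
        )
        if self.pinned:
            s = np.ones_like(s)
        self._s = s
        return x * s[:, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, s = self._x, self._s
        dx = gout * s[:, :, None, None]
        if self.pinned:
            return dx
        ds = (gout * x).sum(axis=(2, 3))
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(
            self.sigmoid.backward(ds))))
        dx += dz[:, :, None, None] / self._hw
        return dx


class Adam:
    """Adam with optional decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            if self.weight_decay:
                p.value *= 1.0 - self.lr * self.weight_decay
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
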