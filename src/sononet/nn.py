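"""Minimal NumPy neural-network layers with explicit backpropagation.

All layers operate on 5D tensors of shape (batch, channels, time, height,
width); purely spatial (2D) networks use a singleton time axis so that a
single code path serves every model variant.  Convolutions are stride-1 with
"same" padding (odd kernels), which is the only configuration the
architectures here require; downsampling is done exclusively by max-pooling.

The implementation favours clarity and determinism over raw speed: convolution
is an im2col (``sliding_window_view``) followed by a BLAS ``tensordot``,
processed one sample at a time to bound peak memory.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._errors import ShapeError

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "BatchNorm",
    "ReLU",
    "MaxPool3d",
    "GlobalAvgPool",
    "Network",
    "Adam",
    "softmax",
    "cross_entropy",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def parameters(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. BN running statistics)."""
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """Stride-1 same-padded 3D convolution (He-initialised, bias optional)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int, int],
        rng: np.random.Generator,
        bias: bool = False,
    ) -> None:
        kt, kh, kw = kernel
        if min(kt, kh, kw) < 1 or kt % 2 == 0 or kh % 2 == 0 or kw % 2 == 0:
            raise ShapeError(f"conv kernel must be odd and >= 1, got {kernel}")
        fan_in = in_channels * kt * kh * kw
        std = math.sqrt(2.0 / fan_in)
        self.kernel = kernel
        self.pad = (kt // 2, kh // 2, kw // 2)
        self.W = Param(
            rng.normal(0.0, std, size=(out_channels, in_channels, kt, kh, kw)).astype(
                np.float32
            ),
            "conv.weight",
        )
        self.b = Param(np.zeros(out_channels, dtype=np.float32), "conv.bias") if bias else None
        self._xp: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pt, ph, pw = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        self._xp = xp if train else None
        W = self.W.value
        n, _, t, h, w = x.shape
        out = np.empty((n, W.shape[0], t, h, w), dtype=np.float32)
        for i in range(n):
            win = sliding_window_view(xp[i], self.kernel, axis=(1, 2, 3))
            out[i] = np.tensordot(W, win, axes=((1, 2, 3, 4), (0, 4, 5, 6)))
        if self.b is not None:
            out += self.b.value[:, None, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._xp is None:
            raise RuntimeError("backward called without a train-mode forward")
        W = self.W.value
        n, _, t, h, w = grad.shape
        dW = np.zeros_like(W)
        for i in range(n):
            # window = output extent -> axes line up as (C, kt, kh, kw, t, h, w)
            winx = sliding_window_view(self._xp[i], (t, h, w), axis=(1, 2, 3))
            dW += np.tensordot(grad[i], winx, axes=((1, 2, 3), (4, 5, 6)))
        self.W.grad += dW
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        # dx = full correlation of grad with the flipped kernel
        Wt = np.ascontiguousarray(W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        pt, ph, pw = self.pad
        gp = np.pad(grad, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        dx = np.empty((n, W.shape[1], t, h, w), dtype=np.float32)
        for i in range(n):
            wing = sliding_window_view(gp[i], self.kernel, axis=(1, 2, 3))
            dx[i] = np.tensordot(Wt, wing, axes=((1, 2, 3, 4), (0, 4, 5, 6)))
        self._xp = None
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalisation over (batch, time, height, width)."""

    _AXES = (0, 2, 3, 4)

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels, dtype=np.float32), "bn.weight")
        self.beta = Param(np.zeros(channels, dtype=np.float32), "bn.bias")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        shape = (1, -1, 1, 1, 1)
        if train:
            mean = x.mean(axis=self._AXES)
            var = x.var(axis=self._AXES)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
            self._cache = (xhat, inv)
            m = self.momentum
            self.running_mean += m * (mean - self.running_mean)
            self.running_var += m * (var - self.running_var)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(shape)) * inv.reshape(shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a train-mode forward")
        xhat, inv = self._cache
        shape = (1, -1, 1, 1, 1)
        self.gamma.grad += (grad * xhat).sum(axis=self._AXES)
        self.beta.grad += grad.sum(axis=self._AXES)
        dxhat = grad * self.gamma.value.reshape(shape)
        mean_d = dxhat.mean(axis=self._AXES).reshape(shape)
        mean_dx = (dxhat * xhat).mean(axis=self._AXES).reshape(shape)
        self._cache = None
        return inv.reshape(shape) * (dxhat - mean_d - xhat * mean_dx)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return grad * mask


class MaxPool3d(Layer):
    """Max pooling with stride equal to the kernel; trailing remainders dropped."""

    def __init__(self, kernel: tuple[int, int, int], name: str = "pool") -> None:
        self.kernel = kernel
        self.name = name
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        kt, kh, kw = self.kernel
        n, c, t, h, w = x.shape
        t2, h2, w2 = t // kt, h // kh, w // kw
        if t2 == 0 or h2 == 0 or w2 == 0:
            raise ShapeError(
                f"input of shape {(t, h, w)} collapses to zero at pooling stage "
                f"'{self.name}' with kernel {self.kernel}"
            )
        xc = x[:, :, : t2 * kt, : h2 * kh, : w2 * kw]
        x6 = (
            xc.reshape(n, c, t2, kt, h2, kh, w2, kw)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, t2, h2, w2, kt * kh * kw)
        )
        idx = x6.argmax(axis=-1)
        if train:
            self._cache = (idx, x.shape)
        return np.take_along_axis(x6, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a train-mode forward")
        idx, in_shape = self._cache
        self._cache = None
        kt, kh, kw = self.kernel
        n, c, t2, h2, w2 = grad.shape
        dx6 = np.zeros((n, c, t2, h2, w2, kt * kh * kw), dtype=grad.dtype)
        np.put_along_axis(dx6, idx[..., None], grad[..., None], axis=-1)
        dxc = (
            dx6.reshape(n, c, t2, h2, w2, kt, kh, kw)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, t2 * kt, h2 * kh, w2 * kw)
        )
        dx = np.zeros(in_shape, dtype=grad.dtype)
        dx[:, :, : t2 * kt, : h2 * kh, : w2 * kw] = dxc
        return dx


class GlobalAvgPool(Layer):
    """Average over all remaining spatio-temporal positions -> (batch, channels)."""

    def __init__(self) -> None:
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, t, h, w = self._in_shape
        scale = 1.0 / (t * h * w)
        return np.broadcast_to(
            (grad * scale)[:, :, None, None, None], self._in_shape
        ).astype(grad.dtype, copy=True)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    # -inf rows from logit masking become exp(nan) otherwise
    z = np.where(np.isneginf(z), -np.inf, z)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = float(-logp[np.arange(n), labels].mean())
    dlogits = np.exp(logp)
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Network:
    """A sequential stack ending in global average pooling (+ softmax on call)."""

    def __init__(self, layers: list[Layer], num_classes: int, spatial_only: bool) -> None:
        self.layers = layers
        self.num_classes = num_classes
        self.spatial_only = spatial_only

    def _prep(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if self.spatial_only and x.ndim == 4:  # (B, C, H, W) -> singleton time axis
            x = x[:, :, None, :, :]
        if x.ndim != 5:
            raise ShapeError(f"expected a 4D/5D batch, got shape {x.shape}")
        return x

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self._prep(x)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return softmax(self.logits(x, train=train), axis=1)

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.parameters()]
        for layer in self.layers:
            state.extend(b.copy() for b in layer.buffers())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, v in zip(params, state[: len(params)]):
            p.value[...] = v
        buffers = [b for layer in self.layers for b in layer.buffers()]
        for b, v in zip(buffers, state[len(params) :]):
            b[...] = v


class Adam(Layer):
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(
        self,
        params: list[Param],
        lr: float,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
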