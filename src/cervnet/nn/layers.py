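"""NumPy layers with explicit forward/backward passes.

Conventions
-----------
* Activations are ``(batch, channels, height, width)`` float64 arrays.
* Convolutions use "same" padding: total pad = dilation·(N−1), split low/high, so a
  stride-1 conv preserves spatial dims and a stride-s conv yields ceil(dim/s).
* ``groups`` is either 1 (dense conv) or ``in_channels`` (depthwise); nothing in the
  network family needs intermediate group counts.

The convolution backward pass uses the standard kernel-tap decomposition: for each of
the N² kernel positions the contribution to the (padded) input gradient is a strided
slice-add of a channel-mixing matmul of the output gradient, which keeps everything
vectorised without a col2im scatter.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import InvalidShapeError
from .core import Module, Parameter

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Dropout",
]


def _same_pad(kernel_size: int, dilation: int) -> tuple[int, int]:
    total = dilation * (kernel_size - 1)
    return total // 2, total - total // 2


class Conv2d(Module):
    """2-D convolution (dense or depthwise) with same padding, no bias by default.

    Parameters
    ----------
    in_channels, out_channels : int
    kernel_size : int
        Odd kernel edge N.
    stride : {1, 2}
    dilation : int
        Spacing between kernel taps; effective receptive field dilation·(N−1)+1.
    groups : int
        1 (dense) or ``in_channels`` (depthwise, requires out == in).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, dilation: int = 1, groups: int = 1, bias: bool = False):
        super().__init__()
        if groups not in (1, in_channels):
            raise InvalidShapeError(f"groups must be 1 or in_channels, got {groups}")
        if groups == in_channels and out_channels != in_channels:
            raise InvalidShapeError("depthwise conv requires out_channels == in_channels")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        self.groups = groups
        self.depthwise = groups == in_channels
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        w = np.random.randn(out_channels, in_channels // groups, kernel_size, kernel_size)
        self.weight = Parameter(w * np.sqrt(2.0 / fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def init_weights(self, rng: np.random.Generator) -> None:
        fan_in = (self.in_channels // self.groups) * self.kernel_size ** 2
        self.weight.data[...] = rng.standard_normal(self.weight.data.shape) * np.sqrt(2.0 / fan_in)
        if self.bias is not None:
            self.bias.data[...] = 0.0

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        return (-(-h // self.stride), -(-w // self.stride))

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.in_channels:
            raise InvalidShapeError(f"expected {self.in_channels} channels, got {c}")
        n, s, d = self.kernel_size, self.stride, self.dilation
        plo, phi = _same_pad(n, d)
        xp = np.pad(x, ((0, 0), (0, 0), (plo, phi), (plo, phi)))
        reach = d * (n - 1) + 1
        win = sliding_window_view(xp, (reach, reach), axis=(2, 3))
        win = win[:, :, ::s, ::s, ::d, ::d]  # (B, C, Ho, Wo, N, N)
        if self.depthwise:
            y = np.einsum("bchwij,cij->bchw", win, self.weight.data[:, 0], optimize=True)
        else:
            y = np.einsum("bchwij,ocij->bohw", win, self.weight.data, optimize=True)
        if self.bias is not None:
            y = y + self.bias.data[None, :, None, None]
        self._cache = (win, xp.shape, x.shape)
        from . import _complexity_recorder
        if _complexity_recorder.active():
            ho, wo = y.shape[2], y.shape[3]
            mults = ho * wo * (self.in_channels // self.groups) * self.out_channels * n * n
            _complexity_recorder.record(self, mults, self.num_parameters())
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        win, xp_shape, x_shape = self._cache
        n, s, d = self.kernel_size, self.stride, self.dilation
        plo, _ = _same_pad(n, d)
        if self.depthwise:
            dw = np.einsum("bchwij,bchw->cij", win, grad_out, optimize=True)
            self.weight.grad += dw[:, None]
        else:
            self.weight.grad += np.einsum("bchwij,bohw->ocij", win, grad_out, optimize=True)
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        b, _, ho, wo = grad_out.shape
        dxp = np.zeros(xp_shape)
        for i in range(n):
            for j in range(n):
                if self.depthwise:
                    contrib = self.weight.data[:, 0, i, j][None, :, None, None] * grad_out
                else:
                    contrib = np.einsum("ocij,bohw->bchw",
                                        self.weight.data[:, :, i:i + 1, j:j + 1],
                                        grad_out, optimize=True)
                r0, c0 = i * d, j * d
                dxp[:, :, r0:r0 + s * ho:s, c0:c0 + s * wo:s] += contrib
        h, w = x_shape[2], x_shape[3]
        return dxp[:, :, plo:plo + h, plo:plo + w]


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics for eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(channels))   # scale (gamma)
        self.bias = Parameter(np.zeros(channels))    # shift (beta)
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def init_weights(self, rng: np.random.Generator) -> None:
        self.weight.data[...] = 1.0
        self.bias.data[...] = 0.0
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise InvalidShapeError(f"expected {self.channels} channels, got {x.shape[1]}")
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var[...] = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, x.shape)
        from . import _complexity_recorder
        if _complexity_recorder.active():
            _complexity_recorder.record(self, 0, self.num_parameters())
        return self.weight.data[None, :, None, None] * xhat + self.bias.data[None, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, std, shape = self._cache
        axes = (0, 2, 3)
        self.weight.grad += (grad_out * xhat).sum(axis=axes)
        self.bias.grad += grad_out.sum(axis=axes)
        dxhat = grad_out * self.weight.data[None, :, None, None]
        if not self.training:
            return dxhat / std[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        mean_d = dxhat.sum(axis=axes, keepdims=True) / m
        mean_dx = (dxhat * xhat).sum(axis=axes, keepdims=True) / m
        return (dxhat - mean_d - xhat * mean_dx) / std[None, :, None, None]


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad_out, 0.0)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._out * (1.0 - self._out)


class MaxPool2d(Module):
    """Max pooling with padding; tied maxima split the gradient evenly."""

    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        n, s, p = self.kernel_size, self.stride, self.padding
        return ((h + 2 * p - n) // s + 1, (w + 2 * p - n) // s + 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        win = sliding_window_view(xp, (n, n), axis=(2, 3))[:, :, ::s, ::s]
        out = win.max(axis=(-2, -1))
        self._cache = (win, out, xp.shape, x.shape)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        win, out, xp_shape, x_shape = self._cache
        n, s, p = self.kernel_size, self.stride, self.padding
        mask = win == out[..., None, None]
        share = grad_out / mask.sum(axis=(-2, -1))
        b, c, ho, wo = grad_out.shape
        dxp = np.zeros(xp_shape)
        for i in range(n):
            for j in range(n):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += mask[..., i, j] * share
        h, w = x_shape[2], x_shape[3]
        return dxp[:, :, p:p + h, p:p + w]


class GlobalAvgPool(Module):
    """(B, C, H, W) -> (B, C) spatial mean; the squeeze step of channel attention."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(grad_out[:, :, None, None], self._shape) / (h * w)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(np.random.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def init_weights(self, rng: np.random.Generator) -> None:
        bound = 1.0 / np.sqrt(self.in_features)
        self.weight.data[...] = rng.uniform(-bound, bound, self.weight.data.shape)
        if self.bias is not None:
            self.bias.data[...] = rng.uniform(-bound, bound, self.bias.data.shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.in_features:
            raise InvalidShapeError(f"expected {self.in_features} features, got {x.shape[-1]}")
        self._x = x
        y = x @ self.weight.data.T
        if self.bias is not None:
            y = y + self.bias.data
        from . import _complexity_recorder
        if _complexity_recorder.active():
            mults = x.shape[-1] * self.out_features
            _complexity_recorder.record(self, mults, self.num_parameters())
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.weight.grad += grad_out.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.data


class Dropout(Module):
    """Inverted dropout; identity at p=0 or in eval mode."""

    def __init__(self, p: float = 0.0, seed: int = 0):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad_out
        return grad_out * self._mask
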