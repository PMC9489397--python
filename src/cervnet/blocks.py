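"""Building blocks of the shuffle-style inverted residual network family.

The stride-1 unit splits its input channels into an identity half and a transformed
half (1×1 conv → depthwise conv → optional channel attention → 1×1 conv, each with
batch norm), concatenates the two halves and mixes them with a two-group channel
shuffle.  The stride-2 unit processes the full input through two parallel branches
and concatenates them, doubling channels while halving the spatial dims.  Channel
attention — squeeze-and-excitation (SE) or selective-kernel (SK) — is inserted on the
depthwise-convolution output inside the transformed branch.

All modules carry explicit backward passes (see :mod:`cervnet.nn`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np

from . import nn
from .errors import ConfigurationError, InvalidGroupsError, InvalidShapeError

__all__ = [
    "FeatureMapSpec", "ConvSpec", "AttentionConfig", "BlockSpec",
    "channel_split", "channel_shuffle", "se_squeeze",
    "ChannelShuffle", "DepthwiseSeparableConv", "SEModule", "SKModule",
    "InvertedResidualUnit", "DownsampleUnit", "make_attention",
]


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureMapSpec:
    """Shape of an activation map: height × width spatial grid with ``channels`` planes."""

    height: int
    width: int
    channels: int

    def __post_init__(self):
        if min(self.height, self.width, self.channels) < 1:
            raise ConfigurationError("feature map dims must all be >= 1")

    def after_stride(self, stride: int) -> "FeatureMapSpec":
        """Spatial dims after a stride-s same-padded op: ceil(dim / s)."""
        return FeatureMapSpec(-(-self.height // stride), -(-self.width // stride), self.channels)


@dataclass(frozen=True)
class ConvSpec:
    """Configuration of a single convolution stage."""

    kernel_size: int
    in_channels: int
    out_channels: int
    stride: int = 1
    dilation: int = 1
    depthwise: bool = False

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigurationError("kernel_size must be a positive odd integer")
        if self.stride not in (1, 2):
            raise ConfigurationError("stride must be 1 or 2")
        if self.dilation < 1:
            raise ConfigurationError("dilation must be >= 1")
        if min(self.in_channels, self.out_channels) < 1:
            raise ConfigurationError("channel counts must be positive")
        if self.depthwise and self.out_channels != self.in_channels:
            raise ConfigurationError("depthwise conv requires out_channels == in_channels")

    @property
    def receptive_field(self) -> int:
        return self.dilation * (self.kernel_size - 1) + 1


@dataclass(frozen=True)
class AttentionConfig:
    """Channel-attention choice: ``none``, ``se`` or ``sk``.

    ``reduction_ratio`` r sets the bottleneck width ceil(C / r) of the excitation
    (never below 1).  ``sk_branch_norm`` selects how the two SK branch scores are
    normalised per channel: ``softmax`` across branches (default; weights sum to 1)
    or an independent ``sigmoid`` per branch.
    """

    kind: str = "none"
    reduction_ratio: int = 16
    sk_branch_norm: str = "softmax"

    def __post_init__(self):
        if self.kind not in ("none", "se", "sk"):
            raise ConfigurationError(f"unknown attention kind {self.kind!r}")
        if self.reduction_ratio < 1:
            raise ConfigurationError("reduction_ratio must be >= 1")
        if self.sk_branch_norm not in ("softmax", "sigmoid"):
            raise ConfigurationError(f"unknown sk_branch_norm {self.sk_branch_norm!r}")

    def bottleneck_width(self, channels: int) -> int:
        return max(1, math.ceil(channels / self.reduction_ratio))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AttentionConfig":
        return cls(**d)


@dataclass(frozen=True)
class BlockSpec:
    """One inverted-residual unit's configuration."""

    channels_in: int
    channels_out: int
    stride: int = 1
    kernel_size: int = 3
    attention: AttentionConfig = field(default_factory=AttentionConfig)

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ConfigurationError("stride must be 1 or 2")
        if self.stride == 1 and self.channels_in != self.channels_out:
            raise ConfigurationError("stride-1 unit requires channels_out == channels_in")
        if self.kernel_size % 2 == 0:
            raise ConfigurationError("kernel_size must be odd")
        if min(self.channels_in, self.channels_out) < 1:
            raise ConfigurationError("channel counts must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BlockSpec":
        d = dict(d)
        if isinstance(d.get("attention"), dict):
            d["attention"] = AttentionConfig.from_dict(d["attention"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "BlockSpec":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# functional primitives
# ---------------------------------------------------------------------------

def channel_split(x: np.ndarray, fractions: Tuple[float, float] = (0.5, 0.5)):
    """Split ``(B, C, H, W)`` into the first ``floor(C·f1)`` channels and the rest.

    Concatenating the two pieces along the channel axis restores the input exactly.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("split fractions must sum to 1")
    c = x.shape[1]
    if c < 2:
        raise InvalidShapeError("channel_split needs at least 2 channels")
    c1 = int(c * fractions[0])
    if c1 < 1 or c1 >= c:
        raise InvalidShapeError(f"split fractions leave an empty half for C={c}")
    return x[:, :c1], x[:, c1:]


def channel_shuffle(x: np.ndarray, groups: int) -> np.ndarray:
    """Group-wise channel permutation: reshape (G, n) → transpose → flatten.

    Output channel ``i·G + g`` is input channel ``g·n + i`` (n = C/G); a pure
    permutation of channels that mixes information across the G groups.
    """
    b, c, h, w = x.shape
    if groups < 1 or c % groups != 0:
        raise InvalidGroupsError(f"channels ({c}) not divisible by groups ({groups})")
    n = c // groups
    return x.reshape(b, groups, n, h, w).transpose(0, 2, 1, 3, 4).reshape(b, c, h, w)


def se_squeeze(u: np.ndarray) -> np.ndarray:
    """Global-average squeeze: per-channel spatial mean, ``(B, C, H, W) -> (B, C)``."""
    if u.ndim != 4 or u.shape[2] < 1 or u.shape[3] < 1:
        raise InvalidShapeError("squeeze expects a (B, C, H, W) map")
    return u.mean(axis=(2, 3))


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class ChannelShuffle(nn.Module):
    """Shuffle as a layer; backward applies the inverse permutation."""

    def __init__(self, groups: int = 2):
        super().__init__()
        self.groups = groups

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._n = x.shape[1] // self.groups
        return channel_shuffle(x, self.groups)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        # shuffling with G groups is inverted by shuffling with n = C/G groups
        return channel_shuffle(grad_out, self._n)


class DepthwiseSeparableConv(nn.Module):
    """Depthwise N×N conv followed by a pointwise 1×1 conv.

    The depthwise stage convolves each input channel with its own single-channel
    kernel; the pointwise stage mixes channels.  Optional batch norm after each
    stage (used inside SK branches).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, dilation: int = 1, norm: bool = False):
        super().__init__()
        self.depthwise = nn.Conv2d(in_channels, in_channels, kernel_size,
                                   stride=stride, dilation=dilation, groups=in_channels)
        self.pointwise = nn.Conv2d(in_channels, out_channels, 1)
        self.norm_dw = nn.BatchNorm2d(in_channels) if norm else None
        self.norm_pw = nn.BatchNorm2d(out_channels) if norm else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.depthwise(x)
        if self.norm_dw is not None:
            y = self.norm_dw(y)
        y = self.pointwise(y)
        if self.norm_pw is not None:
            y = self.norm_pw(y)
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self.norm_pw is not None:
            grad_out = self.norm_pw.backward(grad_out)
        grad_out = self.pointwise.backward(grad_out)
        if self.norm_dw is not None:
            grad_out = self.norm_dw.backward(grad_out)
        return self.depthwise.backward(grad_out)


class SEModule(nn.Module):
    """Squeeze-and-excitation channel attention.

    z = spatial mean of each channel; s = sigmoid(W2·relu(W1·z)) with bottleneck
    width ceil(C/r); output channel c is s_c · U_c.  ``gate_override`` pins every
    gate to a constant (diagnostic hook used to verify the identity/null limits).
    """

    def __init__(self, channels: int, reduction_ratio: int = 16):
        super().__init__()
        self.channels = channels
        width = max(1, math.ceil(channels / reduction_ratio))
        self.pool = nn.GlobalAvgPool()
        self.fc1 = nn.Linear(channels, width)
        self.relu = nn.ReLU()
        self.fc2 = nn.Linear(width, channels)
        self.sigmoid = nn.Sigmoid()
        self.gate_override: Optional[float] = None

    def excite(self, z: np.ndarray) -> np.ndarray:
        """Map squeezed descriptors (B, C) to gates in the open interval (0, 1)."""
        return self.sigmoid(self.fc2(self.relu(self.fc1(z))))

    def forward(self, u: np.ndarray) -> np.ndarray:
        if u.shape[1] != self.channels:
            raise InvalidShapeError(f"expected {self.channels} channels, got {u.shape[1]}")
        if self.gate_override is not None:
            s = np.full((u.shape[0], self.channels), float(self.gate_override))
        else:
            s = self.excite(self.pool(u))
        self._cache = (u, s)
        return u * s[:, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        u, s = self._cache
        du = grad_out * s[:, :, None, None]
        if self.gate_override is not None:
            return du
        ds = (grad_out * u).sum(axis=(2, 3))
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(self.sigmoid.backward(ds))))
        return du + self.pool.backward(dz)


class SKModule(nn.Module):
    """Selective-kernel attention over two depthwise-separable branches.

    Branch 1 uses a 3×3 kernel at dilation 1, branch 2 the same kernel at dilation 2
    (receptive field 5), both padded to keep spatial dims.  Per-channel descriptors of
    the summed branches pass through a shared bottleneck; two heads score the branches
    and the scores are normalised per channel (softmax across branches by default, so
    the weights are convex; independent sigmoids optionally).  The output is the
    weighted sum of the branches.
    """

    def __init__(self, channels: int, reduction_ratio: int = 16,
                 branch_norm: str = "softmax", kernel_size: int = 3):
        super().__init__()
        if branch_norm not in ("softmax", "sigmoid"):
            raise ConfigurationError(f"unknown branch_norm {branch_norm!r}")
        self.channels = channels
        self.branch_norm = branch_norm
        width = max(1, math.ceil(channels / reduction_ratio))
        self.branch1 = DepthwiseSeparableConv(channels, channels, kernel_size,
                                              dilation=1, norm=True)
        self.branch2 = DepthwiseSeparableConv(channels, channels, kernel_size,
                                              dilation=2, norm=True)
        self.pool = nn.GlobalAvgPool()
        self.reduce = nn.Linear(channels, width)
        self.relu = nn.ReLU()
        self.score1 = nn.Linear(width, channels)
        self.score2 = nn.Linear(width, channels)
        self.sig1 = nn.Sigmoid()
        self.sig2 = nn.Sigmoid()
        self.weight_override: Optional[Tuple[float, float]] = None

    def forward(self, u: np.ndarray) -> np.ndarray:
        if u.shape[1] != self.channels:
            raise InvalidShapeError(f"expected {self.channels} channels, got {u.shape[1]}")
        if u.shape[2] < 2 or u.shape[3] < 2:
            raise InvalidShapeError("spatial dims too small for the dilation-2 branch")
        b1 = self.branch1(u)
        b2 = self.branch2(u)
        if self.weight_override is not None:
            w1 = np.full(b1.shape[:2], float(self.weight_override[0]))
            w2 = np.full(b2.shape[:2], float(self.weight_override[1]))
        else:
            h = self.relu(self.reduce(self.pool(b1 + b2)))
            a1, a2 = self.score1(h), self.score2(h)
            if self.branch_norm == "softmax":
                m = np.maximum(a1, a2)
                e1, e2 = np.exp(a1 - m), np.exp(a2 - m)
                w1 = e1 / (e1 + e2)
                w2 = e2 / (e1 + e2)
            else:
                w1, w2 = self.sig1(a1), self.sig2(a2)
        self._cache = (b1, b2, w1, w2)
        return w1[:, :, None, None] * b1 + w2[:, :, None, None] * b2

    def branch_weights(self, u: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Per-channel branch weights (w1, w2) for an input map (runs a forward pass)."""
        self.forward(u)
        _, _, w1, w2 = self._cache
        return w1, w2

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        b1, b2, w1, w2 = self._cache
        db1 = grad_out * w1[:, :, None, None]
        db2 = grad_out * w2[:, :, None, None]
        if self.weight_override is None:
            dw1 = (grad_out * b1).sum(axis=(2, 3))
            dw2 = (grad_out * b2).sum(axis=(2, 3))
            if self.branch_norm == "softmax":
                inner = w1 * dw1 + w2 * dw2
                da1 = w1 * (dw1 - inner)
                da2 = w2 * (dw2 - inner)
            else:
                da1 = self.sig1.backward(dw1)
                da2 = self.sig2.backward(dw2)
            dh = self.score1.backward(da1) + self.score2.backward(da2)
            dz = self.reduce.backward(self.relu.backward(dh))
            dfused = self.pool.backward(dz)
            db1 = db1 + dfused
            db2 = db2 + dfused
        return self.branch1.backward(db1) + self.branch2.backward(db2)


def make_attention(attention: AttentionConfig, channels: int) -> Optional[nn.Module]:
    """Instantiate the configured attention module for a branch of given width."""
    if attention.kind == "none":
        return None
    if attention.kind == "se":
        return SEModule(channels, attention.reduction_ratio)
    return SKModule(channels, attention.reduction_ratio, attention.sk_branch_norm)


class _ConvBN(nn.Sequential):
    def __init__(self, in_c, out_c, kernel=1, stride=1, groups=1, act=True):
        layers = [nn.Conv2d(in_c, out_c, kernel, stride=stride, groups=groups),
                  nn.BatchNorm2d(out_c)]
        if act:
            layers.append(nn.ReLU())
        super().__init__(*layers)


class InvertedResidualUnit(nn.Module):
    """Stride-1 split unit: identity half ∥ transformed half, concat, shuffle(G=2).

    The transformed half runs 1×1 conv+BN+ReLU → depthwise conv+BN → [attention] →
    1×1 conv+BN+ReLU.  Output shape equals input shape.
    """

    def __init__(self, spec: BlockSpec):
        super().__init__()
        if spec.stride != 1:
            raise ConfigurationError("InvertedResidualUnit requires stride 1; "
                                     "use DownsampleUnit for stride 2")
        if spec.channels_in % 2 != 0:
            raise ConfigurationError("split unit requires an even channel count")
        self.spec = spec
        c = spec.channels_in
        self.c1 = c // 2
        branch_w = c - self.c1
        layers = [nn.Conv2d(branch_w, branch_w, 1), nn.BatchNorm2d(branch_w), nn.ReLU(),
                  nn.Conv2d(branch_w, branch_w, spec.kernel_size, groups=branch_w),
                  nn.BatchNorm2d(branch_w)]
        attn = make_attention(spec.attention, branch_w)
        if attn is not None:
            layers.append(attn)
        layers += [nn.Conv2d(branch_w, branch_w, 1), nn.BatchNorm2d(branch_w), nn.ReLU()]
        self.branch = nn.Sequential(*layers)
        self.shuffle = ChannelShuffle(2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.spec.channels_in:
            raise InvalidShapeError(
                f"expected {self.spec.channels_in} channels, got {x.shape[1]}")
        x1, x2 = x[:, :self.c1], x[:, self.c1:]
        y2 = self.branch(x2)
        return self.shuffle(np.concatenate([x1, y2], axis=1))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = self.shuffle.backward(grad_out)
        g1 = g[:, :self.c1]
        g2 = self.branch.backward(g[:, self.c1:])
        return np.concatenate([g1, g2], axis=1)


class DownsampleUnit(nn.Module):
    """Stride-2 unit: two parallel branches over the full input, concat, shuffle(G=2).

    Branch A: depthwise stride-2 conv+BN → 1×1 conv+BN+ReLU.  Branch B: 1×1
    conv+BN+ReLU → depthwise stride-2 conv+BN → [attention] → 1×1 conv+BN+ReLU.
    Spatial dims are halved (ceil); channels become ``channels_out``.
    """

    def __init__(self, spec: BlockSpec):
        super().__init__()
        if spec.stride != 2:
            raise ConfigurationError("DownsampleUnit requires stride 2")
        if spec.channels_out % 2 != 0:
            raise ConfigurationError("downsample unit requires even channels_out")
        self.spec = spec
        cin, half = spec.channels_in, spec.channels_out // 2
        k = spec.kernel_size
        self.branch_a = nn.Sequential(
            nn.Conv2d(cin, cin, k, stride=2, groups=cin), nn.BatchNorm2d(cin),
            nn.Conv2d(cin, half, 1), nn.BatchNorm2d(half), nn.ReLU())
        layers = [nn.Conv2d(cin, half, 1), nn.BatchNorm2d(half), nn.ReLU(),
                  nn.Conv2d(half, half, k, stride=2, groups=half), nn.BatchNorm2d(half)]
        attn = make_attention(spec.attention, half)
        if attn is not None:
            layers.append(attn)
        layers += [nn.Conv2d(half, half, 1), nn.BatchNorm2d(half), nn.ReLU()]
        self.branch_b = nn.Sequential(*layers)
        self.shuffle = ChannelShuffle(2)
        self.half = half

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.spec.channels_in:
            raise InvalidShapeError(
                f"expected {self.spec.channels_in} channels, got {x.shape[1]}")
        if x.shape[2] < 2 or x.shape[3] < 2:
            raise InvalidShapeError("input spatial dims too small to downsample")
        ya = self.branch_a(x)
        yb = self.branch_b(x)
        return self.shuffle(np.concatenate([ya, yb], axis=1))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = self.shuffle.backward(grad_out)
        return (self.branch_a.backward(g[:, :self.half])
                + self.branch_b.backward(g[:, self.half:]))
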