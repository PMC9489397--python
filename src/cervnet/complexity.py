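"""Analytic cost accounting for convolutions and assembled networks.

Costs are counted as the number of scalar multiplications, the convention used when
motivating depthwise-separable convolution: a dense N×N conv over an output grid
W×H costs W·H·C_in·C_out·N², its separable factorisation costs
W·H·C_in·N² (depthwise) + W·H·C_in·C_out (pointwise), and their ratio collapses to
1/C_out + 1/N² independently of W, H and C_in.  Additions and biases are not
counted.  For strided convs the output grid is used for W, H.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from typing import List, Tuple

import numpy as np

from .blocks import ConvSpec, FeatureMapSpec
from .errors import ConfigurationError, UnsupportedLayerError
from . import nn
from .nn import _complexity_recorder

__all__ = ["ComplexityReport", "conv_mults", "dws_mults", "reduction_ratio",
           "model_complexity"]


@dataclass
class ComplexityReport:
    """Per-layer and total multiplication/parameter counts for one network.

    ``size_bytes`` is the serialized parameter size, total_params × precision_bytes
    (default single precision) — a parameter-file size, not peak memory.
    """

    per_layer: List[Tuple[str, str, int, int]]  # (name, kind, mults, params)
    precision_bytes: int = 4

    @property
    def total_mults(self) -> int:
        return sum(e[2] for e in self.per_layer)

    @property
    def total_params(self) -> int:
        return sum(e[3] for e in self.per_layer)

    @property
    def size_bytes(self) -> int:
        return self.total_params * self.precision_bytes

    def to_dict(self) -> dict:
        return {
            "per_layer": [
                {"name": n, "kind": k, "mults": m, "params": p}
                for n, k, m, p in self.per_layer
            ],
            "total_mults": self.total_mults,
            "total_params": self.total_params,
            "size_bytes": self.size_bytes,
            "precision_bytes": self.precision_bytes,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_tsv(self) -> str:
        lines = ["layer\tkind\tmults\tparams"]
        for n, k, m, p in self.per_layer:
            lines.append(f"{n}\t{k}\t{m}\t{p}")
        lines.append(f"TOTAL\t-\t{self.total_mults}\t{self.total_params}")
        lines.append(f"size_bytes\t-\t-\t{self.size_bytes}")
        return "\n".join(lines)


def _out_dims(fmap: FeatureMapSpec, stride: int) -> Tuple[int, int]:
    out = fmap.after_stride(stride)
    return out.width, out.height


def conv_mults(fmap: FeatureMapSpec, spec: ConvSpec) -> int:
    """Multiplications of a dense convolution: W·H·C_in·C_out·N² (output-grid W, H)."""
    if spec.depthwise:
        raise ConfigurationError("conv_mults is for dense convs; use dws_mults")
    if fmap.channels != spec.in_channels:
        raise ConfigurationError("feature map channels != spec.in_channels")
    w, h = _out_dims(fmap, spec.stride)
    return w * h * spec.in_channels * spec.out_channels * spec.kernel_size ** 2


def dws_mults(fmap: FeatureMapSpec, kernel_size: int, out_channels: int,
              stride: int = 1) -> int:
    """Multiplications of a depthwise-separable conv: W·H·C_in·N² + W·H·C_in·C_out."""
    if kernel_size < 1 or out_channels < 1:
        raise ConfigurationError("kernel_size and out_channels must be positive")
    w, h = _out_dims(fmap, stride)
    cin = fmap.channels
    depthwise = w * h * cin * kernel_size ** 2
    pointwise = w * h * cin * out_channels
    return depthwise + pointwise


def reduction_ratio(kernel_size: int, out_channels: int) -> Fraction:
    """Cost ratio (separable / dense) = 1/C_out + 1/N²; W, H, C_in cancel exactly."""
    if kernel_size < 1 or out_channels < 1:
        raise ConfigurationError("kernel_size and out_channels must be positive")
    return Fraction(1, out_channels) + Fraction(1, kernel_size ** 2)


def _supported_leaves():
    from .blocks import ChannelShuffle  # deferred: blocks imports this module's deps
    return (nn.Conv2d, nn.Linear, nn.BatchNorm2d, nn.ReLU, nn.Sigmoid,
            nn.MaxPool2d, nn.GlobalAvgPool, nn.Dropout, ChannelShuffle)


def model_complexity(model: nn.Module, input_spec: FeatureMapSpec,
                     precision_bytes: int = 4) -> ComplexityReport:
    """Walk an assembled network and account every conv/linear/norm layer.

    Runs a single forward pass on a zero batch of the given shape with a recorder
    enabled, so the multiplication counts reflect the true activation shapes at
    every layer (strides, pooling and branching included).
    """
    supported = _supported_leaves()
    names = {}
    for name, m in model.named_modules():
        if not m._modules:  # leaf
            if not isinstance(m, supported):
                raise UnsupportedLayerError(
                    f"layer {name!r} of type {type(m).__name__} is not supported "
                    "by the complexity walker")
            names[id(m)] = name
        else:
            names[id(m)] = name
    x = np.zeros((1, input_spec.channels, input_spec.height, input_spec.width))
    was_training = model.training
    model.eval()
    with _complexity_recorder.recording(names) as rec:
        model(x)
    model.train(was_training)
    return ComplexityReport(per_layer=rec.entries, precision_bytes=precision_bytes)
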