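"""Assemble the classification networks: plain shuffle backbone, SE and SK variants.

Layout: 3×3 stride-2 stem conv (+BN+ReLU) and 3×3 stride-2 max pool, three stages of
[one stride-2 downsample unit followed by (repeat−1) stride-1 split units], a final
1×1 conv (+BN+ReLU), global average pooling and a linear head producing one logit per
class.  Default widths follow the canonical 1.0× schedule for this unit family
(stem 24; stages 4/8/4 deep at 116/232/464 channels; final 1024); the clinical
labelling task fixes ``num_classes`` at 5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Tuple

import numpy as np

from . import nn
from .blocks import AttentionConfig, BlockSpec, DownsampleUnit, InvertedResidualUnit
from .errors import ConfigurationError, InvalidShapeError
from .nn.functional import softmax

__all__ = ["ModelConfig", "ShuffleAttentionNet", "build_model", "predict",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    stem_channels: int = 24
    stage_repeats: Tuple[int, ...] = (4, 8, 4)
    stage_channels: Tuple[int, ...] = (116, 232, 464)
    final_channels: int = 1024
    num_classes: int = 5
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    dropout: float = 0.0
    input_channels: int = 3

    def __post_init__(self):
        if len(self.stage_repeats) != len(self.stage_channels):
            raise ConfigurationError("stage_repeats and stage_channels lengths differ")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        if any(r < 1 for r in self.stage_repeats):
            raise ConfigurationError("stage repeats must be positive")
        if any(c < 2 or c % 2 for c in self.stage_channels):
            raise ConfigurationError("stage channels must be positive and even")
        if min(self.stem_channels, self.final_channels) < 1:
            raise ConfigurationError("channel counts must be positive")
        object.__setattr__(self, "stage_repeats", tuple(self.stage_repeats))
        object.__setattr__(self, "stage_channels", tuple(self.stage_channels))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_repeats"] = list(self.stage_repeats)
        d["stage_channels"] = list(self.stage_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if isinstance(d.get("attention"), dict):
            d["attention"] = AttentionConfig.from_dict(d["attention"])
        return cls(**d)


class ShuffleAttentionNet(nn.Module):
    """The staged shuffle network with optional SE/SK attention in every unit."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        c = config.stem_channels
        self.stem = nn.Sequential(
            nn.Conv2d(config.input_channels, c, 3, stride=2),
            nn.BatchNorm2d(c), nn.ReLU())
        self.pool = nn.MaxPool2d(3, 2, 1)
        stages = []
        cin = c
        for repeat, cout in zip(config.stage_repeats, config.stage_channels):
            units = [DownsampleUnit(BlockSpec(cin, cout, stride=2,
                                              attention=config.attention))]
            for _ in range(repeat - 1):
                units.append(InvertedResidualUnit(BlockSpec(cout, cout, stride=1,
                                                            attention=config.attention)))
            stages.append(nn.Sequential(*units))
            cin = cout
        self.stages = nn.Sequential(*stages)
        self.head_conv = nn.Sequential(
            nn.Conv2d(cin, config.final_channels, 1),
            nn.BatchNorm2d(config.final_channels), nn.ReLU())
        self.global_pool = nn.GlobalAvgPool()
        self.dropout = nn.Dropout(config.dropout)
        self.classifier = nn.Linear(config.final_channels, config.num_classes)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.config.input_channels:
            raise InvalidShapeError(
                f"expected (B, {self.config.input_channels}, H, W) input, got {x.shape}")
        y = self.stem(x)
        y = self.pool(y)
        y = self.stages(y)
        y = self.head_conv(y)
        y = self.global_pool(y)
        y = self.dropout(y)
        return self.classifier(y)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = self.classifier.backward(grad_out)
        g = self.dropout.backward(g)
        g = self.global_pool.backward(g)
        g = self.head_conv.backward(g)
        g = self.stages.backward(g)
        g = self.pool.backward(g)
        return self.stem.backward(g)


def init_weights(model: nn.Module, seed: int = 0) -> None:
    """Re-initialise every layer from one seeded generator (Kaiming convs, unit BN)."""
    rng = np.random.default_rng(seed)
    for _, m in model.named_modules():
        init = getattr(m, "init_weights", None)
        if init is not None:
            init(rng)


def build_model(config: ModelConfig, seed: int = 0) -> ShuffleAttentionNet:
    """Construct a network and deterministically initialise its weights."""
    model = ShuffleAttentionNet(config)
    init_weights(model, seed)
    return model


def predict(model: nn.Module, images: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Eval-mode class predictions for a batch.

    Returns ``(class_indices, probabilities)``; probabilities are the softmax over
    logits (rows sum to 1), classes the argmax with lowest-index tie-break.
    """
    was_training = model.training
    model.eval()
    try:
        logits = model(np.asarray(images, dtype=np.float64))
    finally:
        model.train(was_training)
    probs = softmax(logits, axis=1)
    return np.argmax(probs, axis=1), probs


def save_checkpoint(model: ShuffleAttentionNet, path) -> None:
    """Serialize weights plus the embedded ModelConfig (self-describing checkpoint)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    arrays = {k.replace(":", "__"): v for k, v in state.items()}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ShuffleAttentionNet:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")  # np.savez appends .npz
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig.from_dict(
            json.loads(bytes(data["__config__"]).decode()))
        model = ShuffleAttentionNet(config)
        state = {k.replace("__", ":", 1): data[k] for k in data.files if k != "__config__"}
        model.load_state_dict(state)
    return model
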