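"""Training loop and evaluation driver.

The default recipe follows the clinical study conditions: SGD with Nesterov momentum
0.9, weight decay 1e-4, batch size 32, 100 epochs, initial learning rate 0.05.  The
learning-rate schedule defaults to a linear decay from the initial rate to 0 over
the configured epochs (a constant and a cosine schedule are available).  The loss is
cross-entropy on logits; per-epoch training loss and validation accuracy are
recorded and the best-validation weights are retained.
"""

from __future__ import annotations

import copy
import csv
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import EvalTransform, ImageRecord, TrainTransform
from .errors import ConfigurationError, DivergenceError
from .metrics import ConfusionMatrix, metrics, roc_auc
from .model import ModelConfig, ShuffleAttentionNet, build_model, predict
from .nn import SGD, cross_entropy

__all__ = ["TrainConfig", "TrainHistory", "lr_at", "train", "evaluate",
           "predict_scores", "repeated_runs"]


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    lr_schedule: str = "linear_decay"
    nesterov: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.initial_lr <= 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ConfigurationError("rates must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.lr_schedule not in ("linear_decay", "cosine", "constant"):
            raise ConfigurationError(f"unknown lr_schedule {self.lr_schedule!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Learning rate used for epoch ``epoch`` (0-based)."""
    if epoch < 0 or epoch >= config.epochs:
        raise ConfigurationError(f"epoch {epoch} outside [0, {config.epochs})")
    if config.lr_schedule == "constant":
        return config.initial_lr
    if config.lr_schedule == "cosine":
        return config.initial_lr * 0.5 * (1 + math.cos(math.pi * epoch / config.epochs))
    return config.initial_lr * (1 - epoch / config.epochs)


@dataclass
class TrainHistory:
    rows: List[Dict[str, float]] = field(default_factory=list)  # epoch, lr, train_loss, val_accuracy

    def append(self, epoch: int, lr: float, train_loss: float, val_accuracy: float):
        self.rows.append({"epoch": epoch, "lr": lr, "train_loss": train_loss,
                          "val_accuracy": val_accuracy})

    def to_csv(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["epoch", "lr", "train_loss", "val_accuracy"])
            w.writeheader()
            w.writerows(self.rows)


def _load_batch(records: Sequence[ImageRecord], transform) -> np.ndarray:
    return np.stack([transform(r.load()) for r in records])


def evaluate(model, records: Sequence[ImageRecord], transform: EvalTransform,
             num_classes: int, batch_size: int = 32) -> ConfusionMatrix:
    """Confusion matrix of eval-mode predictions over a record list."""
    y_true, y_pred = [], []
    for i in range(0, len(records), batch_size):
        chunk = records[i:i + batch_size]
        x = _load_batch(chunk, transform)
        pred, _ = predict(model, x)
        y_pred.extend(pred.tolist())
        y_true.extend(r.label for r in chunk)
    return ConfusionMatrix.from_predictions(y_true, y_pred, num_classes)


def predict_scores(model, records: Sequence[ImageRecord], transform: EvalTransform,
                   batch_size: int = 32) -> Tuple[np.ndarray, np.ndarray]:
    """(labels, per-class probabilities) over a record list, eval mode."""
    labels, scores = [], []
    for i in range(0, len(records), batch_size):
        chunk = records[i:i + batch_size]
        _, probs = predict(model, _load_batch(chunk, transform))
        scores.append(probs)
        labels.extend(r.label for r in chunk)
    return np.asarray(labels), np.concatenate(scores, axis=0)


def train(model: ShuffleAttentionNet, train_records: Sequence[ImageRecord],
          val_records: Sequence[ImageRecord], config: TrainConfig,
          train_transform: TrainTransform, eval_transform: EvalTransform,
          verbose: bool = False):
    """Optimise ``model`` in place; returns ``(model, history)``.

    The model ends up holding the best-validation-accuracy weights seen during
    training.  Raises :class:`DivergenceError` if the loss becomes non-finite.
    """
    if not train_records or not val_records:
        raise ConfigurationError("train and validation sets must be non-empty")
    num_classes = model.config.num_classes
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.parameters(), lr=config.initial_lr, momentum=config.momentum,
              weight_decay=config.weight_decay, nesterov=config.nesterov)
    history = TrainHistory()
    best_acc, best_state = -1.0, None
    order = np.arange(len(train_records))
    for epoch in range(config.epochs):
        lr = lr_at(epoch, config)
        opt.lr = lr
        rng.shuffle(order)
        model.train(True)
        losses = []
        for i in range(0, len(order), config.batch_size):
            batch = [train_records[j] for j in order[i:i + config.batch_size]]
            x = _load_batch(batch, train_transform)
            y = np.array([r.label for r in batch])
            logits = model(x)
            loss, dlogits = cross_entropy(logits, y)
            if not np.isfinite(loss):
                raise DivergenceError(epoch, i // config.batch_size)
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        cm = evaluate(model, val_records, eval_transform, num_classes,
                      config.batch_size)
        val_acc = metrics(cm).accuracy
        history.append(epoch, lr, float(np.mean(losses)), val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = copy.deepcopy(model.state_dict())
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.4f}  loss {np.mean(losses):.4f}  "
                  f"val acc {val_acc:.2f}%")
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def repeated_runs(n_runs: int, model_config: ModelConfig, train_records,
                  val_records, config: TrainConfig, train_transform_factory,
                  eval_transform: EvalTransform,
                  base_seed: int = 0) -> Dict[str, Tuple[float, Optional[float]]]:
    """Train ``n_runs`` independently seeded models and summarise metrics mean ± sd.

    ``train_transform_factory(seed)`` must return a fresh training transform so the
    augmentation stream is independent per run.
    """
    from .metrics import summarize_runs
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    results = []
    for run in range(n_runs):
        seed = base_seed + run
        model = build_model(model_config, seed=seed)
        run_cfg = TrainConfig(**{**config.to_dict(), "seed": seed})
        model, _ = train(model, train_records, val_records, run_cfg,
                         train_transform_factory(seed), eval_transform)
        cm = evaluate(model, val_records, eval_transform, model_config.num_classes)
        rep = metrics(cm)
        labels, scores = predict_scores(model, val_records, eval_transform)
        results.append({
            "accuracy": rep.accuracy,
            "macro_precision": rep.macro_precision,
            "macro_recall": rep.macro_recall,
            "macro_f1": rep.macro_f1,
            "macro_auc": roc_auc(scores, labels, "macro"),
        })
    return summarize_runs(results)
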