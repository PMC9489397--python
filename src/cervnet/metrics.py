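"""Multiclass evaluation: confusion matrix, percent metrics, ROC/AUC, run summaries.

Per class k the one-vs-rest marginals of a K×K confusion matrix (rows = true class,
columns = predicted class) are TP = cm[k,k], FP = column k − TP, FN = row k − TP and
TN = total − TP − FP − FN.  Precision, recall and F1 follow the usual percent forms
P = TP/(TP+FP)·100, R = TP/(TP+FN)·100, F1 = 2PR/(P+R); overall accuracy is
trace/total·100.  Macro averages are unweighted class means (micro averages are also
reported; for single-label multiclass, micro P = micro R = accuracy).  AUC is the
one-vs-rest rank statistic with midranks for ties — the probability a random positive
is scored above a random negative, ties counted half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigurationError, InvalidShapeError

__all__ = ["ConfusionMatrix", "per_class_counts", "MetricsReport", "metrics",
           "normalize_cm", "roc_auc", "summarize_runs"]


@dataclass
class ConfusionMatrix:
    """K×K integer count table, rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise InvalidShapeError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ConfigurationError("confusion matrix entries must be >= 0")

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int],
                         num_classes: int) -> "ConfusionMatrix":
        cm = np.zeros((num_classes, num_classes), dtype=np.int64)
        np.add.at(cm, (np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)), 1)
        return cls(cm)

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def per_class_counts(cm: ConfusionMatrix, k: int) -> Tuple[int, int, int, int]:
    """One-vs-rest marginals (TP, FP, FN, TN) for class k."""
    c = cm.counts
    tp = int(c[k, k])
    fp = int(c[:, k].sum()) - tp
    fn = int(c[k, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


@dataclass
class MetricsReport:
    """Percent-scale classification metrics derived from one confusion matrix."""

    accuracy: float
    per_class_precision: List[float]
    per_class_recall: List[float]
    per_class_f1: List[float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    support: List[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, list) else v)
                for k, v in self.__dict__.items()}


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reported as 0")
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy plus per-class/macro/micro precision, recall and F1 (percent)."""
    if cm.total == 0:
        raise ConfigurationError("empty confusion matrix")
    k = cm.num_classes
    prec, rec, f1, support = [], [], [], []
    tp_sum = fp_sum = fn_sum = 0
    for i in range(k):
        tp, fp, fn, _ = per_class_counts(cm, i)
        tp_sum, fp_sum, fn_sum = tp_sum + tp, fp_sum + fp, fn_sum + fn
        p = _safe_ratio(tp, tp + fp, f"class-{i} precision") * 100
        r = _safe_ratio(tp, tp + fn, f"class-{i} recall") * 100
        f = _safe_ratio(2 * p * r, p + r, f"class-{i} F1")
        prec.append(p)
        rec.append(r)
        f1.append(f)
        support.append(tp + fn)
    micro_p = _safe_ratio(tp_sum, tp_sum + fp_sum, "micro precision") * 100
    micro_r = _safe_ratio(tp_sum, tp_sum + fn_sum, "micro recall") * 100
    micro_f = _safe_ratio(2 * micro_p * micro_r, micro_p + micro_r, "micro F1")
    return MetricsReport(
        accuracy=float(np.trace(cm.counts)) / cm.total * 100,
        per_class_precision=prec, per_class_recall=rec, per_class_f1=f1,
        macro_precision=float(np.mean(prec)), macro_recall=float(np.mean(rec)),
        macro_f1=float(np.mean(f1)),
        micro_precision=micro_p, micro_recall=micro_r, micro_f1=micro_f,
        support=support)


def normalize_cm(cm: ConfusionMatrix) -> Tuple[np.ndarray, List[int]]:
    """Row-stochastic matrix (each row / its sum) and the list of empty-row indices.

    The diagonal of the normalised matrix equals per-class recall / 100.
    """
    c = cm.counts.astype(np.float64)
    sums = c.sum(axis=1, keepdims=True)
    empty = [i for i in range(cm.num_classes) if sums[i, 0] == 0]
    if empty:
        warnings.warn(f"rows {empty} have no samples; left as zeros")
    out = np.divide(c, sums, out=np.zeros_like(c), where=sums > 0)
    return out, empty


def _binary_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Rank-statistic AUC with midranks (Mann–Whitney form)."""
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    ranks = rankdata(scores, method="average")
    return (ranks[positives].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_auc(scores: np.ndarray, labels: Sequence[int],
            average: str = "macro") -> float:
    """One-vs-rest AUC of per-class probability scores ``(n, K)``.

    Classes without both a positive and a negative sample are skipped with a
    warning.  ``average``: ``macro`` (mean over valid classes), ``micro`` (all
    binarised decisions pooled), or a class index for a single class.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim != 2 or scores.shape[0] != labels.size:
        raise InvalidShapeError("scores must be (n_samples, n_classes)")
    k = scores.shape[1]
    if isinstance(average, (int, np.integer)):
        pos = labels == int(average)
        if pos.all() or not pos.any():
            raise ConfigurationError(f"class {average} lacks positives or negatives")
        return _binary_auc(scores[:, int(average)], pos)
    if average == "micro":
        pooled_scores = scores.ravel(order="F")
        pooled_pos = np.concatenate([(labels == c) for c in range(k)])
        return _binary_auc(pooled_scores, pooled_pos)
    if average != "macro":
        raise ConfigurationError(f"unknown average {average!r}")
    aucs = []
    for c in range(k):
        pos = labels == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} lacks positives or negatives; skipped in AUC")
            continue
        aucs.append(_binary_auc(scores[:, c], pos))
    if not aucs:
        raise ConfigurationError("no class had both positives and negatives")
    return float(np.mean(aucs))


def summarize_runs(runs: List[Dict[str, float]]) -> Dict[str, Tuple[float, Optional[float]]]:
    """Mean ± sample sd (ddof=1) per metric over repeated runs; sd None for n=1."""
    if not runs:
        raise ConfigurationError("no runs to summarize")
    out: Dict[str, Tuple[float, Optional[float]]] = {}
    for key in runs[0]:
        vals = np.array([r[key] for r in runs], dtype=np.float64)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else None
        out[key] = (float(vals.mean()), sd)
    return out
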