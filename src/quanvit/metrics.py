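"""Confusion-matrix metrics, fold aggregation and model comparison.

Metric conventions (all reported as percentages):

* sensitivity = TP / (TP + FN)          (recall of the positive class)
* specificity = TN / (TN + FP)
* precision   = TP / (TP + FP)
* NPV         = TN / (TN + FN)
* accuracy    = (TP + TN) / total; for a KxK matrix the overall accuracy is
  trace / total, and per-class metrics use the one-vs-rest reduction.

Undefined ratios (zero denominator) are reported as ``None``, never as 0.
Rounding is half-up to two decimals and happens only at the report boundary;
all internal arithmetic is double precision.  Fold summaries use the sample
standard deviation (n - 1 denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "METRIC_NAMES",
    "MetricSet",
    "MultiClassMetrics",
    "confusion_matrix",
    "validate_confusion",
    "one_vs_rest",
    "compute_metrics",
    "fold_mean_sd",
    "aggregate_folds",
    "compare_models",
    "roc_auc",
    "round_half_up",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "npv")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), used at report boundaries."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricSet:
    """One row of a performance table; values in percent, None = undefined."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    npv: float | None

    def rounded(self, ndigits: int = 2) -> "MetricSet":
        return MetricSet(
            **{
                k: (None if v is None else round_half_up(v, ndigits))
                for k, v in asdict(self).items()
            }
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MultiClassMetrics:
    """Per-class one-vs-rest metric rows plus the overall trace accuracy."""

    per_class: tuple[MetricSet, ...]
    overall_accuracy: float

    def rounded(self, ndigits: int = 2) -> "MultiClassMetrics":
        return MultiClassMetrics(
            per_class=tuple(m.rounded(ndigits) for m in self.per_class),
            overall_accuracy=round_half_up(self.overall_accuracy, ndigits),
        )

    def to_dict(self) -> dict:
        return {
            "per_class": [m.to_dict() for m in self.per_class],
            "overall_accuracy": self.overall_accuracy,
        }


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    """Integer count matrix, rows = true class, columns = predicted class."""
    from sklearn.metrics import confusion_matrix as _cm

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    return _cm(y_true, y_pred, labels=np.arange(n_classes))


def validate_confusion(cm) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] < 2:
        raise ValueError("confusion matrix must be square, K >= 2")
    if np.any(cm < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    if cm.sum() == 0:
        raise ValueError("confusion matrix is empty")
    return cm.astype(np.int64)


def one_vs_rest(cm, positive_class: int) -> np.ndarray:
    """Collapse a KxK matrix to 2x2 for one class (positive class first).

    TP = cm[c, c]; FN = rest of row c; FP = rest of column c; TN = remainder.
    The grand total is preserved.
    """
    cm = validate_confusion(cm)
    k = cm.shape[0]
    if not (0 <= positive_class < k):
        raise ValueError(f"class {positive_class} out of range for K={k}")
    c = positive_class
    tp = cm[c, c]
    fn = cm[c, :].sum() - tp
    fp = cm[:, c].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return np.array([[tp, fn], [fp, tn]], dtype=np.int64)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def _binary_metrics(binary_cm: np.ndarray) -> MetricSet:
    (tp, fn), (fp, tn) = binary_cm
    total = tp + fn + fp + tn
    return MetricSet(
        accuracy=_ratio(tp + tn, total),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def compute_metrics(
    cm, positive_class: int | None = None
) -> MetricSet | MultiClassMetrics:
    """Metrics from a confusion matrix.

    2x2 input (or an explicit ``positive_class``) yields a single
    `MetricSet`; a KxK input yields per-class one-vs-rest rows plus the
    overall accuracy (trace / total).
    """
    cm = validate_confusion(cm)
    k = cm.shape[0]
    if k == 2 and positive_class is None:
        positive_class = 0
    if positive_class is not None:
        return _binary_metrics(one_vs_rest(cm, positive_class))
    return MultiClassMetrics(
        per_class=tuple(
            _binary_metrics(one_vs_rest(cm, c)) for c in range(k)
        ),
        overall_accuracy=float(100.0 * np.trace(cm) / cm.sum()),
    )


def fold_mean_sd(values: Sequence[float], ndigits: int = 2) -> tuple[float, float]:
    """Mean and sample SD (n - 1) across folds, rounded half-up."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("at least 2 folds are required")
    return (
        round_half_up(float(values.mean()), ndigits),
        round_half_up(float(values.std(ddof=1)), ndigits),
    )


def aggregate_folds(
    fold_metrics: Sequence[MetricSet | Mapping[str, float]], ndigits: int = 2
) -> dict[str, tuple[float, float]]:
    """Per-metric (mean, sample SD) over k folds."""
    if len(fold_metrics) < 2:
        raise ValueError("at least 2 folds are required")
    rows = [
        m.to_dict() if isinstance(m, MetricSet) else dict(m) for m in fold_metrics
    ]
    out: dict[str, tuple[float, float]] = {}
    for name in rows[0]:
        vals = [r[name] for r in rows]
        if any(v is None for v in vals):
            continue
        out[name] = fold_mean_sd(vals, ndigits)
    return out


def compare_models(
    report_a: Mapping[str, float] | MetricSet,
    report_b: Mapping[str, float] | MetricSet,
    ndigits: int = 2,
) -> dict[str, float]:
    """Metric-wise differences B - A (B conventionally the quantum model)."""
    a = report_a.to_dict() if isinstance(report_a, MetricSet) else dict(report_a)
    b = report_b.to_dict() if isinstance(report_b, MetricSet) else dict(report_b)
    if set(a) != set(b):
        raise ValueError("reports carry different metrics")
    return {
        k: round_half_up(b[k] - a[k], ndigits)
        for k in a
        if a[k] is not None and b[k] is not None
    }


def roc_auc(scores, labels, positive_class: int = 1):
    """ROC curve and area (percent) by threshold sweep.

    ``scores`` are positive-class scores for binary labels; with K > 2,
    pass one-vs-rest scores per class and call once per class.  Returns
    (fpr, tpr, auc_percent).
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = (labels == positive_class).astype(int)
    fpr, tpr, _ = roc_curve(y, scores)
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, 100.0 * area
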