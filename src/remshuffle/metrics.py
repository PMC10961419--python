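"""Multiclass evaluation: confusion matrix, precision/recall/F1/accuracy and
per-crop-group aggregation.

Per class c (one-vs-rest): TP = M[c,c], FP = column sum - TP, FN = row sum -
TP, TN = total - TP - FP - FN, and

    P = TP / (TP + FP),   R = TP / (TP + FN),
    F1 = 2 P R / (P + R), A_ovr = (TP + TN) / total.

Indeterminate 0/0 ratios are defined as 0 (with a warning).  Headline
aggregates are macro (unweighted class means); support-weighted means are
available behind a flag.  Overall accuracy is trace/total, not the mean of
the one-vs-rest accuracies (which inflates with the class count).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_matrix",
    "metrics_from_confusion",
    "per_group_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    matrix: np.ndarray
    precision: np.ndarray       # per class
    recall: np.ndarray
    f1: np.ndarray
    ovr_accuracy: np.ndarray    # per-class one-vs-rest accuracy
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float             # trace / total
    support: np.ndarray         # true count per class
    per_group: dict[str, "MetricsReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "matrix": self.matrix.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "ovr_accuracy": self.ovr_accuracy.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "support": self.support.tolist(),
        }
        if self.per_group:
            d["per_group"] = {g: r.to_dict() for g, r in self.per_group.items()}
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary_row(self) -> dict:
        """P/R/F1/A percentages, one comparison-table-shaped row."""
        return {
            "precision_pct": 100 * self.macro_precision,
            "recall_pct": 100 * self.macro_recall,
            "f1_pct": 100 * self.macro_f1,
            "accuracy_pct": 100 * self.accuracy,
        }


def confusion_matrix(y_true, y_pred, num_classes: int) -> np.ndarray:
    """K x K matrix; entry (i, j) counts samples of true class i predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    for v in (y_true, y_pred):
        if v.min() < 0 or v.max() >= num_classes:
            raise ValueError("label out of range")
    m = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(m, (y_true, y_pred), 1)
    return m


def class_counts(matrix: np.ndarray, c: int) -> ConfusionCounts:
    """One-vs-rest TP/FP/TN/FN for class ``c``."""
    m = np.asarray(matrix)
    tp = int(m[c, c])
    fp = int(m[:, c].sum() - tp)
    fn = int(m[c].sum() - tp)
    tn = int(m.sum() - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    bad = den == 0
    if bad.any():
        warnings.warn(f"{what}: 0/0 for class(es) {np.where(bad)[0].tolist()}; "
                      "defining as 0", stacklevel=3)
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=~bad)
    return out


def metrics_from_confusion(matrix: np.ndarray, *, weighted: bool = False) -> MetricsReport:
    """Full metric suite from a confusion matrix.

    ``weighted=True`` swaps the macro aggregates for support-weighted means.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (m < 0).any():
        raise ValueError("negative counts")
    total = m.sum()
    if total == 0:
        raise ValueError("all-zero confusion matrix")
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = total - tp - fp - fn
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    ovr_acc = (tp + tn) / total
    support = m.sum(axis=1)
    if weighted:
        w = support / total
        agg = lambda v: float((v * w).sum())  # noqa: E731
    else:
        agg = lambda v: float(v.mean())  # noqa: E731
    return MetricsReport(
        matrix=np.asarray(matrix),
        precision=precision, recall=recall, f1=f1, ovr_accuracy=ovr_acc,
        macro_precision=agg(precision), macro_recall=agg(recall),
        macro_f1=agg(f1), accuracy=float(tp.sum() / total),
        support=support.astype(np.int64),
    )


def per_group_metrics(matrix: np.ndarray, grouping: dict[int, str], *,
                      weighted: bool = False) -> dict[str, MetricsReport]:
    """Metrics aggregated within class groups (e.g. classes of one crop).

    Each group's per-class metrics are computed from the full matrix (one vs
    all other classes, in or out of the group) and then macro-averaged over
    the group's member classes.
    """
    k = np.asarray(matrix).shape[0]
    missing = [c for c in range(k) if c not in grouping]
    if missing:
        raise ValueError(f"classes without a group: {missing}")
    full = metrics_from_confusion(matrix, weighted=weighted)
    out: dict[str, MetricsReport] = {}
    for group in dict.fromkeys(grouping.values()):
        idx = np.array([c for c in range(k) if grouping[c] == group])
        sub = MetricsReport(
            matrix=full.matrix,
            precision=full.precision[idx], recall=full.recall[idx],
            f1=full.f1[idx], ovr_accuracy=full.ovr_accuracy[idx],
            macro_precision=float(full.precision[idx].mean()),
            macro_recall=float(full.recall[idx].mean()),
            macro_f1=float(full.f1[idx].mean()),
            accuracy=float(full.ovr_accuracy[idx].mean()),
            support=full.support[idx],
        )
        out[group] = sub
    return out


def evaluate_predictions(y_true, y_pred, num_classes: int, *,
                         grouping: dict[int, str] | None = None,
                         weighted: bool = False) -> MetricsReport:
    """Confusion matrix + metric suite (+ per-group aggregation) in one call."""
    m = confusion_matrix(y_true, y_pred, num_classes)
    report = metrics_from_confusion(m, weighted=weighted)
    if grouping is not None:
        report.per_group = per_group_metrics(m, grouping, weighted=weighted)
    return report
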