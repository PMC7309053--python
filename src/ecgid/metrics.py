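"""Multi-class evaluation: per-class precision/recall, macro averages,
micro accuracy, and the support-weighted F1 score.

Definitions, with one-vs-rest counts tp_c, fp_c, fn_c, tn_c per class c,
n_c samples in class c and N total:

    precision_c = tp_c / (tp_c + fp_c)
    recall_c    = tp_c / (tp_c + fn_c)
    OP = (1/C) * sum_c precision_c          (overall/macro precision)
    OR = (1/C) * sum_c recall_c             (overall/macro recall)
    OA = (sum_c tp_c) / N                   (overall accuracy)
    F1 = sum_c 2 * (n_c/N) * precision_c * recall_c / (precision_c + recall_c)

A class with zero predicted positives contributes precision 0 (and an F1
term of 0) rather than dividing by zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionStats", "EvalReport", "confusion_from_predictions", "report_from_predictions"]


@dataclass
class ConfusionStats:
    """One-vs-rest confusion counts per class plus the raw matrix."""

    matrix: np.ndarray  # (C, C), rows = true class, cols = predicted class

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("confusion matrix must be square")

    @property
    def num_classes(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def fp(self) -> np.ndarray:
        return self.matrix.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.total - self.tp - self.fp - self.fn

    @property
    def support(self) -> np.ndarray:
        """n_c: true sample count per class."""
        return self.matrix.sum(axis=1)


@dataclass
class EvalReport:
    """Per-class and overall classification metrics with the raw counts."""

    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    overall_precision: float
    overall_recall: float
    overall_accuracy: float
    f1_score: float
    confusion: ConfusionStats
    class_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "overall_precision": self.overall_precision,
            "overall_recall": self.overall_recall,
            "f1_score": self.f1_score,
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "class_names": list(self.class_names),
            "confusion_matrix": self.confusion.matrix.tolist(),
        }

    def summary(self) -> str:
        """Human-readable table: OA, OP, OR, F1 then per-class lines."""
        lines = [
            f"{'OA':>4}: {self.overall_accuracy:.4f}",
            f"{'OP':>4}: {self.overall_precision:.4f}",
            f"{'OR':>4}: {self.overall_recall:.4f}",
            f"{'F1':>4}: {self.f1_score:.4f}",
            "class        precision  recall  n",
        ]
        names = self.class_names or [str(i) for i in range(self.confusion.num_classes)]
        for name, p, r, n in zip(
            names, self.per_class_precision, self.per_class_recall, self.confusion.support
        ):
            lines.append(f"{name:<12} {p:9.4f} {r:7.4f}  {int(n)}")
        return "\n".join(lines)


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, num_classes: int
) -> ConfusionStats:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    if y_true.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    matrix = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(matrix, (y_true, y_pred), 1)
    return ConfusionStats(matrix)


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    ok = den > 0
    if not np.all(ok):
        warnings.warn(
            f"{what} undefined for class(es) {np.nonzero(~ok)[0].tolist()}; set to 0",
            stacklevel=3,
        )
    out[ok] = num[ok] / den[ok]
    return out


def report_from_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    num_classes: int,
    class_names: list[str] | None = None,
) -> EvalReport:
    """Build the full metric report from integer label/prediction vectors."""
    conf = confusion_from_predictions(y_true, y_pred, num_classes)
    precision = _safe_div(conf.tp.astype(float), (conf.tp + conf.fp).astype(float), "precision")
    recall = _safe_div(conf.tp.astype(float), (conf.tp + conf.fn).astype(float), "recall")
    op = float(precision.mean())
    orec = float(recall.mean())
    oa = float(conf.tp.sum() / conf.total)
    weight = conf.support / conf.total
    pr_sum = precision + recall
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class_f1 = np.where(pr_sum > 0, 2 * precision * recall / np.where(pr_sum > 0, pr_sum, 1), 0.0)
    f1 = float(np.sum(weight * per_class_f1))
    return EvalReport(
        per_class_precision=precision,
        per_class_recall=recall,
        overall_precision=op,
        overall_recall=orec,
        overall_accuracy=oa,
        f1_score=f1,
        confusion=conf,
        class_names=class_names or [],
    )
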