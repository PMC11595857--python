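"""Confusion-matrix construction and multiclass classification metrics.

Per-class quantities are derived one-vs-rest from the confusion matrix:
TP_c is the diagonal entry, FP_c the rest of column c, FN_c the rest of row
c, TN_c everything else. Then

    accuracy  = (TP + TN) / (TP + TN + FP + FN)   — equals trace/n overall
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 · precision · recall / (precision + recall)

and the per-class values are aggregated by macro (unweighted mean, the
default), micro (pooled counts; collapses to accuracy for single-label
problems) or weighted (support-weighted mean) averaging. A class never
predicted (TP+FP = 0) gets precision 0 with a warning, and likewise for
empty-support recall and degenerate F1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

AVERAGING = ("macro", "micro", "weighted")


@dataclass
class EvaluationReport:
    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str
    per_class: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self, include_per_class: bool = True) -> str:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "averaging": self.averaging,
            "n": int(self.confusion.sum()),
            "confusion": self.confusion.tolist(),
        }
        if include_per_class:
            d["per_class"] = self.per_class
        return json.dumps(d, indent=2)

    def format_table(self) -> str:
        rows = [f"{'metric':<12}{'value':>10}",
                f"{'accuracy':<12}{self.accuracy:>10.4f}",
                f"{'precision':<12}{self.precision:>10.4f}",
                f"{'recall':<12}{self.recall:>10.4f}",
                f"{'f1':<12}{self.f1:>10.4f}",
                f"({self.averaging} averaging, n={int(self.confusion.sum())})"]
        return "\n".join(rows)


def confusion_matrix(true_labels, predicted_labels, num_classes: int) -> np.ndarray:
    """M×M count matrix; entry (i, j) = #{samples with true i predicted j}."""
    t = np.asarray(true_labels, dtype=np.int64).ravel()
    p = np.asarray(predicted_labels, dtype=np.int64).ravel()
    if t.shape != p.shape:
        raise ValueError(
            f"label vectors differ in length: {t.shape[0]} vs {p.shape[0]}")
    for name, arr in (("true", t), ("predicted", p)):
        bad = np.nonzero((arr < 0) | (arr >= num_classes))[0]
        if bad.size:
            raise ValueError(
                f"{name} label out of range [0, {num_classes}) at index "
                f"{int(bad[0])}: {int(arr[bad[0]])}")
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def _safe_div(num, den, what: str):
    out = np.zeros_like(num, dtype=np.float64)
    zero = den == 0
    if np.any(zero):
        warnings.warn(
            f"{what} undefined for class(es) {np.nonzero(zero)[0].tolist()} "
            "(zero denominator); defined as 0", RuntimeWarning, stacklevel=3)
    np.divide(num, den, out=out, where=~zero)
    return out


def classification_metrics(confusion: np.ndarray,
                           averaging: str = "macro") -> EvaluationReport:
    """Evaluate accuracy/precision/recall/F1 from a confusion matrix."""
    if averaging not in AVERAGING:
        raise ValueError(f"averaging must be one of {AVERAGING}, got {averaging!r}")
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {cm.shape}")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    n = cm.sum()
    tp = np.diag(cm).astype(np.float64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    accuracy = float(tp.sum() / n) if n else 0.0
    prec_c = _safe_div(tp, tp + fp, "precision")
    rec_c = _safe_div(tp, tp + fn, "recall")
    f1_c = _safe_div(2 * prec_c * rec_c, prec_c + rec_c, "F1")
    support = cm.sum(axis=1)
    if averaging == "macro":
        precision, recall, f1 = prec_c.mean(), rec_c.mean(), f1_c.mean()
    elif averaging == "weighted":
        w = support / n if n else np.zeros_like(support, dtype=float)
        precision, recall, f1 = (prec_c * w).sum(), (rec_c * w).sum(), (f1_c * w).sum()
    else:  # micro: pool counts over classes
        precision = float(tp.sum() / (tp.sum() + fp.sum())) if n else 0.0
        recall = float(tp.sum() / (tp.sum() + fn.sum())) if n else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
    return EvaluationReport(
        confusion=cm.astype(np.int64),
        accuracy=accuracy, precision=float(precision), recall=float(recall),
        f1=float(f1), averaging=averaging,
        per_class={"precision": prec_c.tolist(), "recall": rec_c.tolist(),
                   "f1": f1_c.tolist(), "support": support.tolist()})


def evaluate_predictions(true_labels, predicted_labels, num_classes: int,
                         averaging: str = "macro") -> EvaluationReport:
    """Convenience wrapper: confusion matrix + metrics in one call."""
    cm = confusion_matrix(true_labels, predicted_labels, num_classes)
    return classification_metrics(cm, averaging)
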