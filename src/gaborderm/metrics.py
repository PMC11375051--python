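"""Confusion matrices, the evaluation-metric suite and per-class ROC/AUC.

Per-class quantities come from a one-vs-rest collapse of the multiclass
confusion matrix (rows = true, columns = predicted, fixed alphabetical
class order).  For each class c:

    sensitivity = TP / (TP + FN)            specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)            F1 = 2 TP / (2 TP + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    accuracy    = (TP + TN) / (TP + TN + FP + FN)

Aggregates are micro-averaged (per-class counts pooled before the
formula), which for single-label multiclass data forces
precision = sensitivity = F1 = accuracy; the reported MCC is the mean of
the per-class one-vs-rest values.  Macro averages are available behind
``average='macro'``.  ROC curves are one-vs-rest over all unique score
thresholds with trapezoidal AUC (scikit-learn's convention: ties share a
threshold, so constant scores give AUC 0.5 exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from gaborderm.data import CLASSES

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "ROCData",
    "confusion_matrix",
    "compute_metrics",
    "roc_curves",
]


@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = true class, columns = predicted."""

    counts: np.ndarray
    classes: tuple = CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts must be {k}x{k} for {k} classes, "
                f"got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def one_vs_rest(self, i: int) -> tuple:
        """(TP, TN, FP, FN) for class index i."""
        tp = self.counts[i, i]
        fp = self.counts[:, i].sum() - tp
        fn = self.counts[i, :].sum() - tp
        tn = self.counts.sum() - tp - fp - fn
        return int(tp), int(tn), int(fp), int(fn)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass
class EvalReport:
    """The aggregate metric bundle plus per-class vectors."""

    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    specificity: float
    mcc: float
    per_class: pd.DataFrame
    average: str = "micro"
    auc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
            "specificity": self.specificity,
            "mcc": self.mcc,
        }
        out.update({f"auc_{c}": v for c, v in self.auc.items()})
        return out


@dataclass
class ROCData:
    """One-vs-rest ROC point sequences and AUC per class."""

    curves: dict  # class -> (fpr array, tpr array)
    auc: dict  # class -> float


def confusion_matrix(y_true, y_pred, classes=CLASSES) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


def _binary_metrics(tp, tn, fp, fn) -> dict:
    def safe(num, den):
        return num / den if den > 0 else 0.0

    mcc_den = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    return {
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "precision": safe(tp, tp + fp),
        "f1": safe(2 * tp, 2 * tp + fp + fn),
        "mcc": (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else 0.0,
        "accuracy": safe(tp + tn, tp + tn + fp + fn),
    }


def compute_metrics(cm: ConfusionMatrix, average: str = "micro") -> EvalReport:
    """Per-class one-vs-rest metrics plus micro (or macro) aggregates.

    MCC is always reported as the mean of the per-class one-vs-rest
    values (the printed binary formula applied class-wise).
    """
    if cm.counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    rows = []
    pooled = np.zeros(4, dtype=float)
    for i, c in enumerate(cm.classes):
        tp, tn, fp, fn = cm.one_vs_rest(i)
        pooled += (tp, tn, fp, fn)
        rows.append({"class": c, **_binary_metrics(tp, tn, fp, fn)})
    per_class = pd.DataFrame(rows).set_index("class")
    mcc = float(per_class["mcc"].mean())

    if average == "micro":
        agg = _binary_metrics(*pooled)
    elif average == "macro":
        agg = per_class.mean().to_dict()
    else:
        raise ValueError(f"unknown average {average!r}")

    accuracy = float(np.trace(cm.counts) / cm.counts.sum())
    return EvalReport(
        accuracy=accuracy,
        precision=float(agg["precision"]),
        sensitivity=float(agg["sensitivity"]),
        f1=float(agg["f1"]),
        specificity=float(agg["specificity"]),
        mcc=mcc,
        per_class=per_class,
        average=average,
    )


def roc_curves(scores, y_true, classes=CLASSES) -> ROCData:
    """One-vs-rest ROC curves over all score thresholds, trapezoidal AUC.

    ``scores`` is an n x n_classes real matrix whose column order matches
    ``classes``; classes absent from ``y_true`` are skipped.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.shape[0] != len(y_true):
        raise ValueError("scores and y_true disagree on the sample count")
    curves, aucs = {}, {}
    for i, c in enumerate(classes):
        pos = y_true == c
        if pos.all() or not pos.any():
            continue
        fpr, tpr, _ = _sk_roc_curve(pos.astype(int), scores[:, i])
        curves[c] = (fpr, tpr)
        aucs[c] = float(_trapezoid_auc(fpr, tpr))
    return ROCData(curves=curves, auc=aucs)
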