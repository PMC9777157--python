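"""Confusion matrices, one-vs-rest per-class metrics, macro averages, ROC/AUC.

All rate metrics are reported as percentages in [0, 100]. Multiclass
specificity (and the TP/TN/FP/FN bookkeeping generally) uses the
one-vs-rest reduction of the confusion matrix. Zero-denominator cases yield
0 with a warning flag rather than NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .errors import InvalidInputError


def confusion(y_true, y_pred, k: int) -> np.ndarray:
    """k x k integer matrix; entry (i, j) counts true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("label vectors must have equal length")
    for name, v in (("true", y_true), ("predicted", y_pred)):
        if v.size and (v.min() < 0 or v.max() >= k):
            raise InvalidInputError(f"{name} labels outside 0..{k - 1}")
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def ovr_counts(cm: np.ndarray, c: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, FN, TN) for class ``c``."""
    cm = np.asarray(cm)
    tp = int(cm[c, c])
    fn = int(cm[c].sum() - tp)
    fp = int(cm[:, c].sum() - tp)
    tn = int(cm.sum() - tp - fn - fp)
    return tp, fp, fn, tn


def _rate(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return 100.0 * num / den, False


@dataclass
class ClassMetrics:
    label: int
    recall: float
    precision: float
    specificity: float
    f1: float
    accuracy: float
    support: int
    zero_division: bool = False
    auc: float | None = None


@dataclass
class MetricsReport:
    confusion_matrix: np.ndarray
    per_class: list[ClassMetrics]
    accuracy: float                # overall % of correctly classified samples
    macro_recall: float
    macro_precision: float
    macro_specificity: float
    macro_f1: float
    macro_auc: float | None = None
    roc_points: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion_matrix.tolist(),
            "accuracy": self.accuracy,
            "macro": {
                "recall": self.macro_recall,
                "precision": self.macro_precision,
                "specificity": self.macro_specificity,
                "f1": self.macro_f1,
                "auc": self.macro_auc,
            },
            "per_class": [
                {
                    "label": m.label,
                    "recall": m.recall,
                    "precision": m.precision,
                    "specificity": m.specificity,
                    "f1": m.f1,
                    "accuracy": m.accuracy,
                    "support": m.support,
                    "auc": m.auc,
                    "zero_division": m.zero_division,
                }
                for m in self.per_class
            ],
        }

    def save_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = self.to_dict()
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2))


def per_class_metrics(cm: np.ndarray) -> list[ClassMetrics]:
    """One-vs-rest recall/precision/specificity/F1/accuracy per class, in %."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise InvalidInputError("confusion matrix is empty")
    out = []
    for c in range(cm.shape[0]):
        tp, fp, fn, tn = ovr_counts(cm, c)
        recall, z1 = _rate(tp, tp + fn)
        precision, z2 = _rate(tp, tp + fp)
        specificity, z3 = _rate(tn, tn + fp)
        acc, _ = _rate(tp + tn, total)
        if precision + recall > 0:
            f1 = 2.0 * precision * recall / (precision + recall)
            z4 = False
        else:
            f1, z4 = 0.0, True
        out.append(
            ClassMetrics(
                label=c,
                recall=recall,
                precision=precision,
                specificity=specificity,
                f1=f1,
                accuracy=acc,
                support=int(cm[c].sum()),
                zero_division=z1 or z2 or z3 or z4,
            )
        )
    return out


def macro_average(values, decimals: int = 1) -> float:
    """Unweighted arithmetic mean, rounded for reporting (1 decimal default)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise InvalidInputError("macro average of an empty value list")
    return float(np.round(values.mean(), decimals))


def roc_auc(y_true, scores, k: int) -> tuple[dict[int, float], float | None, dict]:
    """Per-class one-vs-rest AUC via the trapezoidal ROC rule.

    Returns (per-class AUCs, macro AUC over defined classes, ROC point sets).
    Classes absent from (or filling) the truth vector get no AUC and are
    excluded from the macro.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[1] != k:
        raise InvalidInputError(f"scores must be (n, {k})")
    if not np.all(np.isfinite(scores)):
        raise InvalidInputError("scores must be finite")
    aucs: dict[int, float] = {}
    points = {}
    for c in range(k):
        positives = y_true == c
        if positives.all() or not positives.any():
            continue  # one-vs-rest AUC undefined
        fpr, tpr, _ = _roc_curve(positives.astype(int), scores[:, c])
        aucs[c] = float(_trapezoid_auc(fpr, tpr))
        points[c] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    macro = float(np.mean(list(aucs.values()))) if aucs else None
    return aucs, macro, points


def full_report(y_true, y_pred, k: int, scores: np.ndarray | None = None) -> MetricsReport:
    cm = confusion(y_true, y_pred, k)
    per_class = per_class_metrics(cm)
    accuracy = 100.0 * np.trace(cm) / cm.sum()
    roc_points = {}
    macro_auc = None
    if scores is not None:
        aucs, macro_auc, roc_points = roc_auc(y_true, scores, k)
        for m in per_class:
            m.auc = aucs.get(m.label)
    return MetricsReport(
        confusion_matrix=cm,
        per_class=per_class,
        accuracy=float(accuracy),
        macro_recall=macro_average([m.recall for m in per_class]),
        macro_precision=macro_average([m.precision for m in per_class]),
        macro_specificity=macro_average([m.specificity for m in per_class]),
        macro_f1=macro_average([m.f1 for m in per_class]),
        macro_auc=macro_auc,
        roc_points=roc_points,
    )
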