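"""Binary classification metrics, ROC/AUC, and model-comparison reports.

Positive class is recurrence throughout.  Ratios with a zero denominator are
reported as 0.0 together with a ``degenerate`` flag instead of raising, so
batch comparisons over many models stay total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass
class EvaluationReport:
    model_label: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: Optional[float] = None
    roc_points: Optional[list[tuple[float, float]]] = None
    confusion: Optional[ConfusionMatrix] = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = {
            "model": self.model_label,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "degenerate": self.degenerate,
        }
        if self.confusion is not None:
            d["confusion"] = {
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tp": self.confusion.tp,
            }
        if self.roc_points is not None:
            d["roc_points"] = [[float(a), float(b)] for a, b in self.roc_points]
        return d


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr.astype(int)


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return ConfusionMatrix(
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
        tp=int(np.sum((yt == 1) & (yp == 1))),
    )


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, precision, recall, F1 from counts.

    Returns a dict with the four metrics plus ``degenerate``: True when any
    ratio had a zero denominator (that metric is reported as 0.0).
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    degenerate = False
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        precision, degenerate = 0.0, True
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "degenerate": degenerate,
    }


def roc_curve_and_auc(y_true, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) thresholded at unique scores, and trapezoidal AUC.

    Equal scores are grouped into a single threshold step; the curve starts at
    (0, 0) and ends at (1, 1).
    """
    yt = _as_binary(y_true, "y_true")
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise ValueError("y_true and scores must have the same length")
    n_pos = int(yt.sum())
    n_neg = int(yt.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = yt[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep only the last index of each tied-score group
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), yt.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate_predictions(
    y_true, y_pred, scores=None, model_label: str = "model"
) -> EvaluationReport:
    """Full report from hard predictions and optional ranking scores."""
    cm = confusion_matrix(y_true, y_pred)
    m = classification_metrics(cm)
    roc_points, auc = (None, None)
    if scores is not None:
        roc_points, auc = roc_curve_and_auc(y_true, scores)
    return EvaluationReport(
        model_label=model_label,
        accuracy=m["accuracy"],
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        auc=auc,
        roc_points=roc_points,
        confusion=cm,
        degenerate=m["degenerate"],
    )


def comparison_report(reports: Sequence[EvaluationReport]) -> dict:
    """Model-comparison table: integer-percent display plus raw values.

    Returns ``{"rows": [...], "markdown": str}`` where each row keeps both the
    rounded display strings (accuracy/precision/recall/F1 as whole percents,
    AUC to two decimals) and the unrounded metrics.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for r in reports:
        rows.append(
            {
                "model": r.model_label,
                "display": {
                    "accuracy": f"{round(r.accuracy * 100):.0f}%",
                    "precision": f"{round(r.precision * 100):.0f}%",
                    "recall": f"{round(r.recall * 100):.0f}%",
                    "f1": f"{round(r.f1 * 100):.0f}%",
                    "auc": "-" if r.auc is None else f"{r.auc:.2f}",
                },
                "raw": r.to_dict(),
            }
        )
    header = "| Model | Accuracy | Precision | Recall | F1 Score | AUC-ROC |"
    sep = "|---|---|---|---|---|---|"
    lines = [header, sep]
    for row in rows:
        d = row["display"]
        lines.append(
            f"| {row['model']} | {d['accuracy']} | {d['precision']} "
            f"| {d['recall']} | {d['f1']} | {d['auc']} |"
        )
    return {"rows": rows, "markdown": "\n".join(lines)}
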