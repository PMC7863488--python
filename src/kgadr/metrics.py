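"""Confusion-matrix metrics, ROC curve and trapezoidal AUC.

The ROC curve is traced over every distinct score threshold (a prediction
is positive when score >= threshold, so tied scores count positive), and
AUC is the trapezoidal area under it — which, with ties contributing one
half, equals the concordance probability P(score_pos > score_neg) +
0.5 P(tie).  Precision, recall and F-score use the textbook formulas with
a fixed threshold; zero-denominator cases return 0 with a warning rather
than propagating NaN.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_at_threshold",
    "precision_recall_f",
    "roc_curve",
    "auc",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN at one threshold; sums to the number of scored pairs."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvalReport:
    """AUC, ROC points and thresholded P/R/F for one test set."""

    auc: float
    roc: tuple[tuple[float, float], ...]
    precision: float
    recall: float
    f_score: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "threshold": self.threshold,
        }

    def save(self, path: str | Path, roc_path: str | Path | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")
        if roc_path is not None:
            with open(roc_path, "w", encoding="utf-8") as fh:
                fh.write("fpr,tpr\n")
                for fpr, tpr in self.roc:
                    fh.write(f"{fpr!r},{tpr!r}\n")


def _check(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    if not set(np.unique(labels).tolist()) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    return scores, labels.astype(int)


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Counts with prediction positive iff score >= threshold."""
    scores, labels = _check(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def precision_recall_f(counts: ConfusionCounts) -> tuple[float, float, float]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R)."""

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} denominator is zero; returning 0", stacklevel=3)
            return 0.0
        return num / den

    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = _ratio(counts.tp, counts.tp + counts.fn, "recall")
    if precision + recall == 0.0:
        warnings.warn("F-score denominator is zero; returning 0", stacklevel=2)
        f = 0.0
    else:
        f = 2 * precision * recall / (precision + recall)
    return precision, recall, f


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> list[tuple[float, float]]:
    """(FPR, TPR) staircase from (0,0) to (1,1), one step per distinct score."""
    scores, labels = _check(scores, labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist()))


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Trapezoidal area under the ROC curve."""
    points = roc_curve(scores, labels)
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return float(np.trapezoid(tpr, fpr))


def evaluate(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> EvalReport:
    """Full report: AUC, ROC points and P/R/F at the given threshold."""
    points = roc_curve(scores, labels)
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    counts = confusion_at_threshold(scores, labels, threshold)
    precision, recall, f = precision_recall_f(counts)
    return EvalReport(
        auc=float(np.trapezoid(tpr, fpr)),
        roc=tuple(points),
        precision=precision,
        recall=recall,
        f_score=f,
        threshold=threshold,
    )
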