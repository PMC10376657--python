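"""Confusion matrices, per-class rate metrics and ROC/AUC.

For each class the validation confusion counts give the true positive
rate TPR = TP / (TP + FN), false negative rate FNR = FN / (TP + FN),
positive predictive value PPV = TP / (TP + FP) and false discovery rate
FDR = FP / (TP + FP), all reported as percentages rounded half-up to one
decimal (so 18/160 = 11.25% prints as 11.3).  Overall accuracy is
100 * sum(TP) / N.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMetrics",
    "UndefinedMetricError",
    "confusion",
    "eq1_metrics",
    "roc_auc",
    "round_half_up",
]

CLASSES = ("RHLF", "RHTF")


class UndefinedMetricError(ValueError):
    """A rate metric has a zero denominator for some class."""


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (2.25 -> 2.3 at one decimal)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def confusion(
    true_labels, pred_labels, classes: tuple[str, ...] = CLASSES
) -> pd.DataFrame:
    """Count table with true classes as rows and predictions as columns."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("label vectors must have equal length")
    known = set(classes)
    bad = (set(true_labels.tolist()) | set(pred_labels.tolist())) - known
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected {classes}")
    counts = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=np.int64)
    for t, p in zip(true_labels, pred_labels):
        counts.loc[t, p] += 1
    counts.index.name = "true"
    counts.columns.name = "predicted"
    return counts


@dataclass(frozen=True)
class ConfusionMetrics:
    """Per-class counts and percentage rates, plus overall accuracy."""

    counts: pd.DataFrame
    tp: dict
    fn: dict
    fp: dict
    tpr: dict
    fnr: dict
    ppv: dict
    fdr: dict
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "counts": {t: dict(row) for t, row in self.counts.iterrows()},
            "TPR_pct": self.tpr, "FNR_pct": self.fnr,
            "PPV_pct": self.ppv, "FDR_pct": self.fdr,
            "accuracy_pct": self.accuracy,
        }

    def to_table(self) -> str:
        """Plain-text report, one row per class."""
        lines = [f"{'Class':<6} {'TP':>4} {'FN':>4} {'FP':>4} "
                 f"{'TPR%':>6} {'FNR%':>6} {'PPV%':>6} {'FDR%':>6}"]
        for c in self.counts.index:
            lines.append(
                f"{c:<6} {self.tp[c]:>4} {self.fn[c]:>4} {self.fp[c]:>4} "
                f"{self.tpr[c]:>6.1f} {self.fnr[c]:>6.1f} "
                f"{self.ppv[c]:>6.1f} {self.fdr[c]:>6.1f}"
            )
        lines.append(f"Overall accuracy: {self.accuracy:.1f}%")
        return "\n".join(lines)


def eq1_metrics(counts: pd.DataFrame) -> ConfusionMetrics:
    """Rate metrics from a square confusion-count table.

    Every class must have at least one real instance and at least one
    prediction; otherwise the corresponding rate is undefined and an
    ``UndefinedMetricError`` is raised rather than returning NaN.
    """
    classes = list(counts.index)
    n_total = int(counts.to_numpy().sum())
    tp, fn, fp, tpr, fnr, ppv, fdr = {}, {}, {}, {}, {}, {}, {}
    for c in classes:
        tp_c = int(counts.loc[c, c])
        real = int(counts.loc[c].sum())
        pred = int(counts[c].sum())
        if real == 0:
            raise UndefinedMetricError(f"class {c!r} has no real instances; TPR/FNR undefined")
        if pred == 0:
            raise UndefinedMetricError(f"class {c!r} was never predicted; PPV/FDR undefined")
        tp[c] = tp_c
        fn[c] = real - tp_c
        fp[c] = pred - tp_c
        tpr[c] = round_half_up(100.0 * tp_c / real)
        fnr[c] = round_half_up(100.0 * (real - tp_c) / real)
        ppv[c] = round_half_up(100.0 * tp_c / pred)
        fdr[c] = round_half_up(100.0 * (pred - tp_c) / pred)
    accuracy = round_half_up(100.0 * sum(tp.values()) / n_total)
    return ConfusionMetrics(
        counts=counts, tp=tp, fn=fn, fp=fp,
        tpr=tpr, fnr=fnr, ppv=ppv, fdr=fdr, accuracy=accuracy,
    )


def roc_auc(
    scores: np.ndarray,
    true_labels: np.ndarray,
    positive_class: str = "RHTF",
) -> tuple[float, pd.DataFrame]:
    """ROC curve and area under it for one positive class.

    The AUC equals the probability that a randomly drawn positive
    outscores a randomly drawn negative, ties counted one half.
    """
    true_labels = np.asarray(true_labels)
    scores = np.asarray(scores, dtype=np.float64)
    y = (true_labels == positive_class).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    value = float(_sk_auc(fpr, tpr))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return value, points
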