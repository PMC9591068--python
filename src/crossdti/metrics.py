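"""Binary-classification metrics for DTI evaluation.

Sensitivity, specificity, precision and F1 are computed from the
confusion table:

    SN = TP / (TP + FN)      SP = TN / (TN + FP)
    PR = TP / (TP + FP)      F1 = 2 PR SN / (PR + SN)

with threshold 0.5 by default (scores exactly at the threshold count as
positive predictions). ROCAUC and PRAUC are threshold-free; PRAUC uses
step-wise average precision by default — the robust choice for the
negative-skewed test sets this method targets — with trapezoidal
precision-recall integration available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (auc, average_precision_score,
                             precision_recall_curve, roc_auc_score)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    SN: float
    SP: float
    PR: float
    F1: float
    ROCAUC: float
    PRAUC: float

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k))
                for k in ("SN", "SP", "PR", "F1", "ROCAUC", "PRAUC")}


def confusion_counts(y_true: np.ndarray, scores: np.ndarray,
                     threshold: float = 0.5) -> ConfusionCounts:
    """Threshold scores (ties -> positive) and tabulate the confusion."""
    y = np.asarray(y_true).astype(int)
    pred = (np.asarray(scores) >= threshold).astype(int)
    return ConfusionCounts(
        TP=int(((y == 1) & (pred == 1)).sum()),
        TN=int(((y == 0) & (pred == 0)).sum()),
        FP=int(((y == 0) & (pred == 1)).sum()),
        FN=int(((y == 1) & (pred == 0)).sum()))


def threshold_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(SN, SP, PR, F1) from a confusion table; 0/0 ratios yield 0."""
    sn = c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0
    sp = c.TN / (c.TN + c.FP) if c.TN + c.FP else 0.0
    pr = c.TP / (c.TP + c.FP) if c.TP + c.FP else 0.0
    f1 = 2 * pr * sn / (pr + sn) if pr + sn else 0.0
    return sn, sp, pr, f1


def evaluate_scores(y_true: np.ndarray, scores: np.ndarray,
                    threshold: float = 0.5,
                    prauc_mode: str = "step") -> MetricSet:
    """All six metrics from true labels and probability scores."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("AUC metrics undefined on a single-class set")
    sn, sp, pr, f1 = threshold_metrics(confusion_counts(y, s, threshold))
    rocauc = float(roc_auc_score(y, s))
    if prauc_mode == "step":
        prauc = float(average_precision_score(y, s))
    elif prauc_mode == "trapezoid":
        precision, recall, _ = precision_recall_curve(y, s)
        prauc = float(auc(recall, precision))
    else:
        raise ValueError(f"unknown prauc_mode {prauc_mode!r}")
    return MetricSet(SN=sn, SP=sp, PR=pr, F1=f1, ROCAUC=rocauc, PRAUC=prauc)


def average_metrics(runs: list[MetricSet]) -> MetricSet:
    """Arithmetic mean of each metric over repeated runs."""
    if not runs:
        raise ValueError("no runs to average")
    return MetricSet(**{k: float(np.mean([m.as_dict()[k] for m in runs]))
                        for k in runs[0].as_dict()})
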