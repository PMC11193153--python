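"""Binary-classification metrics with 'toxic' as the positive class.

Threshold metrics follow the printed formulas exactly:
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
F1 = TP/(TP + (FP+FN)/2), and
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Ranking metrics (auROC by the trapezoid rule, auPRC as average precision)
come from scikit-learn.  Zero-denominator ratios are reported as 0 and
flagged rather than raised, so a degenerate classifier still yields a
complete report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import LengthMismatch

__all__ = ["MetricsReport", "confusion_counts", "compute_metrics"]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    auroc: float
    auprc: float
    n: int
    warnings: list = field(default_factory=list)

    def as_dict(self):
        return asdict(self)

    def as_markdown(self):
        """One-row metrics table in the style of a benchmark comparison."""
        head = ("| Method | Sensitivity | Specificity | F1-score | MCC "
                "| auROC | auPRC |")
        rule = "|---" * 7 + "|"
        row = (f"| peptox | {100*self.sensitivity:.1f} "
               f"| {100*self.specificity:.1f} | {100*self.f1:.1f} "
               f"| {100*self.mcc:.1f} | {100*self.auroc:.1f} "
               f"| {100*self.auprc:.1f} |")
        return "\n".join([head, rule, row])


def _as_binary(values):
    arr = np.asarray(values)
    if arr.dtype.kind in "UO":
        arr = (arr == "toxic").astype(int)
    return arr.astype(int)


def confusion_counts(labels, predictions):
    """(TP, FP, TN, FN) with toxic (1) as the positive class."""
    y = _as_binary(labels)
    pred = _as_binary(predictions)
    if len(y) != len(pred):
        raise LengthMismatch("labels and predictions differ in length")
    tp = int(np.sum((y == 1) & (pred == 1)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    return tp, fp, tn, fn


def compute_metrics(labels, scores, threshold=0.5) -> MetricsReport:
    """Full metrics report from true labels and toxicity scores in [0, 1].

    A sample is predicted toxic iff its score is strictly greater than the
    threshold.  Single-class label vectors leave auROC/auPRC undefined;
    they are reported as 0 with a 'degenerate_labels' warning.
    """
    y = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if len(y) != len(scores):
        raise LengthMismatch("labels and scores differ in length")
    warnings = []
    pred = (scores > threshold).astype(int)
    tp, fp, tn, fn = confusion_counts(y, pred)

    def ratio(num, den, name):
        if den == 0:
            warnings.append(f"undefined_{name}")
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    f1 = ratio(tp, tp + 0.5 * (fp + fn), "f1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        warnings.append("undefined_mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den

    if len(np.unique(y)) < 2:
        warnings.append("degenerate_labels")
        auroc = auprc = 0.0
    else:
        auroc = float(roc_auc_score(y, scores))
        auprc = float(average_precision_score(y, scores))

    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, f1=f1, mcc=mcc,
        auroc=auroc, auprc=auprc, n=len(y), warnings=warnings,
    )
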