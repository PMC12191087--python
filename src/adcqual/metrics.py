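"""Binary classification metrics: confusion-matrix rates and rank AUC.

The positive class throughout the package is "non-diagnostic" (collapsed
quality 1), so sensitivity is the detection rate of problematic scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int
    n: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "npv": self.npv, "ppv": self.ppv,
            "specificity": self.specificity, "sensitivity": self.sensitivity,
            "auc": self.auc, "tp": self.tp, "fp": self.fp, "tn": self.tn,
            "fn": self.fn, "n": self.n,
        }


def binary_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) statistic with
    midrank tie handling. ``labels`` are 0/1 with 1 the positive class."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def _rate(num, den):
    if den == 0:
        warnings.warn("undefined rate (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Confusion counts at ``threshold`` (score >= threshold is called
    positive/non-diagnostic) plus the threshold-free rank AUC."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = len(labels)
    return MetricReport(
        accuracy=_rate(tp + tn, n),
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
        auc=binary_auc(scores, labels),
        tp=tp, fp=fp, tn=tn, fn=fn, n=n,
    )
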