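"""Binary-classification evaluation: ROC/AUC, threshold metrics, and a
stratified bootstrap confidence interval for the AUC.

The AUC is the rank-based pairwise concordance probability (half credit
for score ties), so it equals the Mann-Whitney U of the scores divided
by n1*n0 - a cross-module identity the test suite checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class Metrics:
    """Confusion counts at a threshold and the derived rates.

    Rates with a zero denominator are NaN ("undefined marker")."""

    auc: float
    ci_low: float
    ci_high: float
    f1: float
    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("auc", "ci_low", "ci_high", "f1", "precision", "sensitivity",
                 "specificity", "accuracy", "tp", "fp", "tn", "fn")}


def _check_two_classes(labels):
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels


def roc_auc(scores, labels) -> float:
    """Rank-based AUC with half credit for ties."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores, labels):
    """(fpr, tpr, thresholds) of the ROC curve, for CSV export."""
    labels = _check_two_classes(labels)
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, dtype=float))
    return fpr, tpr, thr


def _safe_div(num, den):
    return float(num) / den if den > 0 else float("nan")


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int,
                        auc: float = float("nan"),
                        ci=(float("nan"), float("nan"))) -> Metrics:
    """Rates from confusion counts: precision TP/(TP+FP), sensitivity
    TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/N, and F1 as the
    harmonic mean of precision and sensitivity."""
    precision = _safe_div(tp, tp + fp)
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    accuracy = _safe_div(tp + tn, tp + fp + tn + fn)
    if np.isfinite(precision) and np.isfinite(sensitivity) \
            and precision + sensitivity > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        f1 = float("nan")
    return Metrics(auc=auc, ci_low=ci[0], ci_high=ci[1], f1=f1,
                   precision=precision, sensitivity=sensitivity,
                   specificity=specificity, accuracy=accuracy,
                   tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))


def threshold_metrics(scores, labels, threshold: float = 0.5,
                      with_auc: bool = True, n_boot: int = 2000,
                      seed: int = 0) -> Metrics:
    """Confusion counts of ``scores >= threshold`` against binary labels,
    plus AUC and its bootstrap CI when both classes are present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    auc, ci = float("nan"), (float("nan"), float("nan"))
    if with_auc and len(np.unique(labels)) == 2:
        auc = roc_auc(scores, labels)
        ci = auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    return metrics_from_counts(tp, fp, tn, fn, auc=auc, ci=ci)


def auc_ci(scores, labels, n_boot: int = 2000, level: float = 0.95,
           seed: int = 0):
    """Stratified percentile bootstrap interval for the AUC: resample
    positives and negatives separately with replacement ``n_boot`` times;
    degenerate resamples are redrawn."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    rng = np.random.default_rng(seed)
    stats_ = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        s = np.concatenate([bp, bn])
        y = np.concatenate([np.ones(len(bp)), np.zeros(len(bn))])
        stats_[b] = roc_auc_score(y, s)
    lo = float(np.percentile(stats_, 100 * (1 - level) / 2))
    hi = float(np.percentile(stats_, 100 * (1 + level) / 2))
    return lo, hi
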