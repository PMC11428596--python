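"""Classifier evaluation: confusion metrics, fold statistics, ROC/AUC and
time-before-onset accuracy profiling.

Conventions that matter for comparability with published fold tables:
means are arithmetic means of the per-fold values; variances are *sample*
variances (divisor n-1) computed on the fractional scale (0.9712, not
97.12).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = ["MetricSet", "FoldSummary", "metrics_from_counts", "fold_summary",
           "roc_auc", "span_accuracy"]


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity and accuracy with their confusion counts.

    Sen = TP/(TP+FN); Spe = TN/(TN+FP); Acc = (TP+TN)/(TP+FN+TN+FP),
    evaluated in exact rational arithmetic before conversion to float.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    sen: float
    spe: float
    acc: float


def metrics_from_counts(tp: int, fn: int, tn: int, fp: int) -> MetricSet:
    """Compute Sen/Spe/Acc from confusion counts (fractions in [0, 1])."""
    for name, v in (("TP", tp), ("FN", fn), ("TN", tn), ("FP", fp)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if tp + fn == 0:
        raise ValueError("no positive examples (TP+FN = 0): sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no negative examples (TN+FP = 0): specificity undefined")
    sen = Fraction(tp, tp + fn)
    spe = Fraction(tn, tn + fp)
    acc = Fraction(tp + tn, tp + fn + tn + fp)
    return MetricSet(tp=tp, fn=fn, tn=tn, fp=fp,
                     sen=float(sen), spe=float(spe), acc=float(acc))


@dataclass(frozen=True)
class FoldSummary:
    """Cross-validation summary: per-fold metrics, means and variances.

    ``*_values`` are fractions per fold; means are fractions; variances
    are sample variances on the fractional scale.
    """

    sen_values: tuple[float, ...]
    spe_values: tuple[float, ...]
    acc_values: tuple[float, ...]
    sen_mean: float
    spe_mean: float
    acc_mean: float
    sen_var: float
    spe_var: float
    acc_var: float


def fold_summary(sen, spe, acc) -> FoldSummary:
    """Aggregate per-fold Sen/Spe/Acc fractions.

    Accepts the three per-fold value sequences (fractions in [0, 1]).
    Requires at least two folds, otherwise the sample variance is
    undefined.
    """
    sen = np.asarray(sen, dtype=np.float64)
    spe = np.asarray(spe, dtype=np.float64)
    acc = np.asarray(acc, dtype=np.float64)
    if not (len(sen) == len(spe) == len(acc)):
        raise ValueError("per-fold metric sequences must have equal length")
    if len(sen) < 2:
        raise ValueError(f"need at least 2 folds for a sample variance, got {len(sen)}")
    return FoldSummary(
        sen_values=tuple(sen), spe_values=tuple(spe), acc_values=tuple(acc),
        sen_mean=float(sen.mean()), spe_mean=float(spe.mean()), acc_mean=float(acc.mean()),
        sen_var=float(sen.var(ddof=1)), spe_var=float(spe.var(ddof=1)),
        acc_var=float(acc.var(ddof=1)),
    )


def roc_auc(labels, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and area by threshold sweep and trapezoid rule.

    Returns (fpr, tpr, auc). The curve is traced over the unique score
    values in decreasing order, anchored at (0,0) and (1,1). Both classes
    must be present.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    pos = int(y.sum())
    neg = len(y) - pos
    if pos == 0 or neg == 0:
        raise ValueError("ROC requires both classes present in labels")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(1 - y_sorted)
    # keep one operating point per unique score (the last index of each run)
    last_of_run = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tpr = np.r_[0.0, tp_cum[last_of_run] / pos]
    fpr = np.r_[0.0, fp_cum[last_of_run] / neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def span_accuracy(time_to_onset, y_true, y_pred, bin_width_s: float = 300.0,
                  span_range_s: tuple[float, float] = (2700.0, 4500.0)) -> pd.DataFrame:
    """Prediction accuracy bucketed by time before AF onset.

    Windows are grouped by ``time_to_onset`` into bins of ``bin_width_s``
    covering ``span_range_s`` (default 45--75 minutes, 5-minute bins).
    Returns a frame with bin edges, window count and accuracy; an empty
    bin reports NaN accuracy (missing, not zero).
    """
    tto = np.asarray(time_to_onset, dtype=np.float64)
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if not (len(tto) == len(yt) == len(yp)):
        raise ValueError("inputs must have equal length")
    if np.any(np.isnan(tto)):
        raise ValueError("time_to_onset must be present (non-NaN) for every window")
    lo, hi = span_range_s
    edges = np.arange(lo, hi + bin_width_s / 2, bin_width_s)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (tto >= a) & (tto < b)
        n = int(mask.sum())
        acc = float(np.mean(yt[mask] == yp[mask])) if n else float("nan")
        rows.append({"span_lo_s": a, "span_hi_s": b, "n_windows": n, "accuracy": acc})
    return pd.DataFrame(rows)
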