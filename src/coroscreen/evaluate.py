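"""Classification metrics, cutoff sweeps, bootstrap intervals, grouped reports.

One canonical ROC AUC is used throughout: the Mann-Whitney pair statistic
(concordant pairs count 1, ties 1/2), equivalent to the trapezoidal area
under the empirical ROC curve.  Precision-recall AUC is the step-integrated
average precision.  Intervals are percentile bootstrap over case-level
resamples, as published figures are (10,000 iterations there; configurable
here).  A probability exactly at a cutoff counts as a positive call.
Undefined metrics (empty denominators) are reported as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "confusion_at_cutoff",
    "classification_metrics",
    "roc_auc",
    "pr_auc",
    "roc_curve_points",
    "bootstrap_interval",
    "cutoff_sweep",
    "metrics_report",
    "grouped_report",
    "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float = 0.5

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_inputs(probs, labels):
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have the same length")
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return probs, labels.astype(int)


def confusion_at_cutoff(probs, labels, cutoff: float = 0.5) -> ConfusionMatrix:
    """Counts with 'predicted positive iff prob >= cutoff'."""
    probs, labels = _check_inputs(probs, labels)
    pred = probs >= cutoff
    return ConfusionMatrix(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
        cutoff=float(cutoff),
    )


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Point metrics from a confusion matrix; empty denominators give NaN."""
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = ratio(cm.tp, cm.tp + cm.fn)
    spec = ratio(cm.tn, cm.tn + cm.fp)
    ppv = ratio(cm.tp, cm.tp + cm.fp)
    acc = ratio(cm.tp + cm.tn, cm.n)
    f1 = (2 * ppv * sens / (ppv + sens)) if (ppv + sens) > 0 else float("nan")
    return {"sensitivity": sens, "specificity": spec, "ppv": ppv, "accuracy": acc, "f1": f1}


def roc_auc(probs, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    probs, labels = _check_inputs(probs, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(probs)                     # midranks handle ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pr_auc(probs, labels) -> float:
    """Average precision: sum over recall steps of precision at that step."""
    probs, labels = _check_inputs(probs, labels)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("pr_auc requires both classes present")
    order = np.argsort(-probs, kind="stable")
    y = labels[order]
    p_sorted = probs[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    recall = tp / n_pos
    # at tied scores only the last point of the tie block is on the curve
    distinct = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    rec = recall[distinct]
    prec = precision[distinct]
    rec_prev = np.r_[0.0, rec[:-1]]
    return float(np.sum((rec - rec_prev) * prec))


def roc_curve_points(probs, labels):
    """(fpr, tpr) points of the empirical ROC curve, cutoffs descending."""
    probs, labels = _check_inputs(probs, labels)
    order = np.argsort(-probs, kind="stable")
    y = labels[order]
    p_sorted = probs[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    distinct = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / max(tp[-1], 1)]
    fpr = np.r_[0.0, fp[distinct] / max(fp[-1], 1)]
    return fpr, tpr


def bootstrap_interval(metric_fn, probs, labels, n_iter: int = 10_000, seed: int = 0,
                       kind: str = "confidence", alpha: float = 0.05, max_retries: int = 100):
    """Case-level percentile bootstrap.

    ``kind='confidence'`` returns the (alpha/2, 1-alpha/2) percentile
    interval of ``metric_fn`` over resamples.  ``kind='tolerance'`` returns
    a pointwise percentile band of resampled ROC curves on an FPR grid
    (grid, low, high) for plot shading.  Resamples holding a single class
    are redrawn up to ``max_retries`` times.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    probs, labels = _check_inputs(probs, labels)
    rng = np.random.default_rng(seed)
    n = len(probs)
    both_classes = 0 < labels.sum() < n

    def draw():
        for attempt in range(max_retries):
            idx = rng.integers(0, n, size=n)
            if not both_classes or 0 < labels[idx].sum() < n:
                if attempt:
                    log.debug("redrew %d single-class bootstrap resample(s)", attempt)
                return idx
        raise RuntimeError("could not draw a two-class bootstrap resample")

    if kind == "confidence":
        stats = np.empty(n_iter)
        for i in range(n_iter):
            idx = draw()
            stats[i] = metric_fn(probs[idx], labels[idx])
        lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return float(lo), float(hi)
    if kind == "tolerance":
        grid = np.linspace(0.0, 1.0, 101)
        curves = np.empty((n_iter, grid.size))
        for i in range(n_iter):
            idx = draw()
            fpr, tpr = roc_curve_points(probs[idx], labels[idx])
            curves[i] = np.interp(grid, fpr, tpr)
        lo, hi = np.percentile(curves, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
        return grid, lo, hi
    raise ValueError("kind must be 'confidence' or 'tolerance'")


def cutoff_sweep(probs, labels, cutoffs=DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Confusion counts + point metrics per cutoff (default grid 0.1..0.9)."""
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("cutoffs must be non-empty")
    rows = []
    for c in cutoffs:
        cm = confusion_at_cutoff(probs, labels, c)
        row = {"cutoff": float(c), "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn}
        row.update(classification_metrics(cm))
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_report(probs, labels, cutoff: float = 0.5, n_boot: int = 0, seed: int = 0) -> dict:
    """Full metric set at a cutoff, with optional bootstrap 95% intervals."""
    probs, labels = _check_inputs(probs, labels)
    cm = confusion_at_cutoff(probs, labels, cutoff)
    report = classification_metrics(cm)
    two_class = 0 < labels.sum() < len(labels)
    report["roc_auc"] = roc_auc(probs, labels) if two_class else float("nan")
    report["aupr"] = pr_auc(probs, labels) if two_class else float("nan")
    report["n"] = cm.n
    report["cutoff"] = float(cutoff)
    if n_boot > 0 and two_class:
        lo, hi = bootstrap_interval(roc_auc, probs, labels, n_boot, seed)
        report["roc_auc_ci"] = (lo, hi)
        report["n_boot"] = n_boot
    return report


def grouped_report(predictions: pd.DataFrame, group_key: str, prob_col: str = "ensemble_prob",
                   label_col: str = "y_true", cutoff: float = 0.5, n_boot: int = 0,
                   seed: int = 0) -> dict:
    """Metrics per group value plus pooled; single-class groups get NaN AUC."""
    if group_key not in predictions.columns:
        raise ValueError(f"group column {group_key!r} missing from predictions")
    out = {"pooled": metrics_report(predictions[prob_col], predictions[label_col],
                                    cutoff, n_boot, seed)}
    for value, sub in predictions.groupby(group_key):
        out[str(value)] = metrics_report(sub[prob_col], sub[label_col], cutoff, n_boot, seed)
    return out
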