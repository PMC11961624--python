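"""Plot files for evaluation outputs (ROC curves, confusion matrices)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import bootstrap_interval, confusion_at_cutoff, roc_auc, roc_curve_points

__all__ = ["save_roc_plot", "save_confusion_plot"]


def save_roc_plot(probs, labels, path, n_boot: int = 0, seed: int = 0, title: str = "ROC"):
    """ROC curve with optional shaded bootstrap tolerance band."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    fpr, tpr = roc_curve_points(probs, labels)
    auc = roc_auc(probs, labels)
    if n_boot > 0:
        grid, lo, hi = bootstrap_interval(roc_auc, probs, labels, n_boot, seed,
                                          kind="tolerance")
        ax.fill_between(grid, lo, hi, color="gray", alpha=0.3, label="tolerance band")
    ax.plot(fpr, tpr, lw=1.5, label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.7)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_confusion_plot(probs, labels, path, cutoff: float = 0.5, title: str = ""):
    cm = confusion_at_cutoff(probs, labels, cutoff)
    mat = np.array([[cm.tn, cm.fp], [cm.fn, cm.tp]])
    fig, ax = plt.subplots(figsize=(3.5, 3.2))
    ax.imshow(mat, cmap="Blues")
    for (i, j), v in np.ndenumerate(mat):
        ax.text(j, i, str(v), ha="center", va="center",
                color="white" if v > mat.max() / 2 else "black")
    ax.set_xticks([0, 1], ["pred neg", "pred pos"])
    ax.set_yticks([0, 1], ["true neg", "true pos"])
    ax.set_title(title or f"cutoff = {cutoff}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
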