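"""Plot helpers for pipeline reports: ablation curves, ROC, confusion."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_ablation_curve", "plot_roc", "plot_confusion"]


def plot_ablation_curve(curve, ax=None):
    """Accuracy versus selected-feature count, one line per kernel."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for kernel, accs in curve.accuracy.items():
        ax.plot(curve.ks, accs, marker="o", label=kernel)
    ax.set_xlabel("number of selected features")
    ax.set_ylabel("test accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_roc(roc, ax=None):
    """One-vs-rest ROC curves with per-class AUC in the legend."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    for cls, (fpr, tpr) in roc.curves.items():
        ax.plot(fpr, tpr, label=f"{cls} (AUC {roc.auc[cls]:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    return ax


def plot_confusion(cm, ax=None):
    """Heatmap of the confusion counts with cell annotations."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(len(cm.classes)), cm.classes, rotation=45)
    ax.set_yticks(range(len(cm.classes)), cm.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    vmax = cm.counts.max() or 1
    for i in range(len(cm.classes)):
        for j in range(len(cm.classes)):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center",
                    color="white" if cm.counts[i, j] > vmax / 2 else "black",
                    fontsize=7)
    plt.colorbar(im, ax=ax, fraction=0.046)
    return ax
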