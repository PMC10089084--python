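"""Thin plotting layer for the analysis artifacts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_elimination_trace",
    "plot_confusion",
    "plot_prediction_histogram",
    "plot_pca_scores",
]


def plot_elimination_trace(trace_frame: pd.DataFrame, path) -> None:
    """Accuracy versus number of classes along the elimination trace."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    df = trace_frame.sort_values("n_classes")
    ax.plot(df["n_classes"], 100 * df["accuracy"], "o-")
    ax.set_xlabel("number of barcode classes")
    ax.set_ylabel("test accuracy (%)")
    ax.set_ylim(0, 105)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_confusion(cm, path) -> None:
    """Heatmap of the confusion matrix (rows true, cols predicted)."""
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(cm.counts, cmap="viridis")
    ax.set_xticks(range(len(cm.classes)), cm.classes, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cm.classes)), cm.classes, fontsize=7)
    ax.set_xlabel("predicted barcode")
    ax.set_ylabel("true barcode")
    fig.colorbar(im, ax=ax, label="particles")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_prediction_histogram(hist: pd.Series, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar([str(i) for i in hist.index], hist.to_numpy())
    ax.set_xlabel("predicted barcode")
    ax.set_ylabel("particles")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca_scores(result, labels: np.ndarray | None, path) -> None:
    """3-D scatter of the top three principal-component scores."""
    fig = plt.figure(figsize=(5.5, 5))
    ax = fig.add_subplot(projection="3d")
    s = result.scores
    c = labels if labels is not None else "k"
    p = ax.scatter(s[:, 0], s[:, 1], s[:, 2], c=c, s=3, cmap="tab20", alpha=0.6)
    pct = result.explained_pct
    ax.set_xlabel(f"PC1 ({pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pct[1]:.1f}%)")
    ax.set_zlabel(f"PC3 ({pct[2]:.1f}%)")
    if labels is not None:
        fig.colorbar(p, ax=ax, shrink=0.6, label="barcode")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
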