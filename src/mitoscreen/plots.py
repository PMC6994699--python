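"""Figure output: ROC curves and correlation heatmaps (SVG/PNG)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .classify import ClassificationReport  # noqa: E402
from .stats import CorrelationReport  # noqa: E402

__all__ = ["plot_roc", "plot_correlation_heatmap"]


def plot_roc(reports: list[ClassificationReport], path: str | Path) -> Path:
    """ROC curves for one or more classification modes.

    The chance diagonal is drawn in black; each report contributes one
    step curve labelled with its mode and AUC.
    """
    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    ax.plot([0, 1], [0, 1], color="black", lw=1, label="chance (AUC = 0.5)")
    for rep, color in zip(reports, ("tab:cyan", "navy", "tab:orange")):
        ax.step(rep.fpr, rep.tpr, where="post", color=color,
                label=f"{rep.mode or 'scores'} (AUC = {rep.auc:.2f})")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_correlation_heatmap(report: CorrelationReport,
                             path: str | Path) -> Path:
    """Pearson correlation heatmap in clustering leaf order, with the
    coefficients printed in each cell."""
    order = report.leaf_order
    r = report.r.loc[order, order]
    n = len(order)
    fig, ax = plt.subplots(figsize=(0.55 * n + 2, 0.55 * n + 2))
    im = ax.imshow(r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(n), order, rotation=90, fontsize=7)
    ax.set_yticks(range(n), order, fontsize=7)
    for i in range(n):
        for j in range(n):
            ax.text(j, i, f"{r.iat[i, j]:.2f}", ha="center", va="center",
                    fontsize=6,
                    color="white" if abs(r.iat[i, j]) > 0.6 else "black")
    fig.colorbar(im, ax=ax, shrink=0.8, label="Pearson r")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
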