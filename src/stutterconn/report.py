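"""Figure outputs: coefficient heatmap, selection-frequency scree, scatter fits."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bootstrap import SelectionReport
from .connectivity import DesignMatrix

__all__ = ["coefficient_heatmap", "selection_scree", "connection_scatter"]


def coefficient_heatmap(
    reports: Mapping[str, SelectionReport], path: str | Path
) -> None:
    """Outcomes x predictors heatmap of mean bootstrap coefficients.

    Stable-set cells are outlined.
    """
    outcomes = list(reports)
    labels = list(next(iter(reports.values())).labels)
    M = np.vstack([reports[o].mean_coef for o in outcomes])
    vmax = max(np.abs(M).max(), 1e-12)
    fig, ax = plt.subplots(figsize=(max(8, len(labels) * 0.22), 2.5 + 0.4 * len(outcomes)))
    im = ax.imshow(M, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(len(outcomes)), outcomes)
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=5)
    for i, o in enumerate(outcomes):
        stable = set(reports[o].stable_set)
        for j, lbl in enumerate(labels):
            if lbl in stable:
                ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1,
                                           fill=False, edgecolor="black", lw=1.5))
    fig.colorbar(im, ax=ax, label="mean bootstrap coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def selection_scree(report: SelectionReport, path: str | Path, title: str = "") -> None:
    """Selection counts in decreasing order with the first-drop cutoff marked."""
    counts = report.ranking["selection_count"].to_numpy()
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(np.arange(1, len(counts) + 1), counts, "o-", ms=3, lw=0.8)
    if report.cutoff_index > 0:
        ax.plot(report.cutoff_index, counts[report.cutoff_index - 1], "ro", ms=8,
                label=f"cutoff (rank {report.cutoff_index})")
        ax.legend()
    ax.set_xlabel("stability rank")
    ax.set_ylabel("selection count")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def connection_scatter(
    design: DesignMatrix,
    predictors: Sequence[str],
    path: str | Path,
) -> None:
    """Outcome vs connectivity scatter with a least-squares line per predictor."""
    preds = [p for p in predictors if p in design.column_labels]
    if not preds:
        return
    fig, axes = plt.subplots(1, len(preds), figsize=(4 * len(preds), 3.5), squeeze=False)
    for ax, lbl in zip(axes[0], preds):
        j = design.column_labels.index(lbl)
        x = design.X[:, j]
        ax.scatter(x, design.y, s=18)
        if x.std() > 0:
            b1, b0 = np.polyfit(x, design.y, 1)
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, b0 + b1 * xs, "k-", lw=1)
        ax.set_xlabel(f"{lbl} (Fisher z)")
        ax.set_ylabel(f"{design.outcome} %")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
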