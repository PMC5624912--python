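"""Optional figure exports: correlogram and marker heat map PNGs."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cluster import CorrelationMatrix
from .io import ExpressionMatrix
from .markers import heatmap_matrix

__all__ = ["plot_correlogram", "plot_marker_heatmap"]


def plot_correlogram(pcc: CorrelationMatrix, path: str | Path,
                     order: Sequence[str] | None = None) -> Path:
    """Cell-by-cell PCC heat map, optionally in dendrogram leaf order."""
    ids = list(order) if order is not None else list(pcc.cell_ids)
    idx = [pcc.cell_ids.index(c) for c in ids]
    values = pcc.values[idx][:, idx]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="Pearson correlation")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def plot_marker_heatmap(mat: ExpressionMatrix, genes: Sequence[str],
                        cell_order: Sequence[str], path: str | Path) -> Path:
    """log2(FPKM+1) heat map of selected genes in the given cell order."""
    values = heatmap_matrix(mat, genes, cell_order)
    fig, ax = plt.subplots(figsize=(8, 0.3 * len(genes) + 1.5))
    im = ax.imshow(values, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(genes)), labels=list(genes), fontsize=7)
    ax.set_xticks([])
    fig.colorbar(im, ax=ax, label="log2(FPKM + 1)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
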