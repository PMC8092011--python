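"""Minimal plotting helpers: atlas heatmap and metric scatter plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .expression import ClusterResult, minmax_normalize
from .io import ExpressionAtlas


def atlas_heatmap(
    atlas: ExpressionAtlas,
    path: str | Path,
    cluster: ClusterResult | None = None,
    normalize: bool = True,
) -> None:
    """Gene x domain heatmap, rows optionally ordered by a clustering."""
    shown = minmax_normalize(atlas) if normalize else atlas
    order = cluster.row_order if cluster is not None else shown.genes
    data = shown.data.loc[order]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.18 * len(order))))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis", vmin=0)
    ax.set_xticks(range(len(shown.domains)), shown.domains, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="normalised expression")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def relative_pare_scatter(
    table: pd.DataFrame,
    covariate: str,
    path: str | Path,
    threshold: float | None = 0.5,
) -> None:
    """Relative PARE frequency against one covariate; optional reference line."""
    sub = table[["relative_pare", covariate]].dropna()
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(sub[covariate], sub["relative_pare"], s=14, alpha=0.7)
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=1, label=f"relative PARE = {threshold}")
        ax.legend(fontsize=8)
    ax.set_xlabel(covariate)
    ax.set_ylabel("relative PARE frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
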