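"""Presentation-layer figures: clustered heatmaps and 2-D embeddings.

These are untested numerically — the quantities they display are computed
(and tested) elsewhere; this module only renders them to SVG/PNG.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering

import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

from .cohort import CASE

__all__ = ["save_clustermap", "save_embedding"]

_PALETTE = {"case": "#d95f02", "control": "#1b9e77"}


def save_clustermap(features: pd.DataFrame, labels: pd.Series, path: str | Path) -> None:
    """Average-linkage / Manhattan clustermap of a sample x feature matrix."""
    colors = labels.loc[features.index].map(_PALETTE)
    grid = sns.clustermap(
        features,
        method="average",
        metric="cityblock",
        row_colors=colors,
        cmap="RdBu_r",
        vmin=0.0,
        vmax=1.0,
    )
    grid.savefig(path)
    plt.close(grid.figure)


def save_embedding(coords: pd.DataFrame, labels: pd.Series, path: str | Path) -> None:
    """Scatter a 2-D embedding (e.g. :func:`episig.evaluate.embed_2d`)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    lab = labels.loc[coords.index]
    for group, marker in ((CASE, "o"), ("control", "s")):
        sub = coords[lab == group]
        ax.scatter(
            sub.iloc[:, 0], sub.iloc[:, 1],
            c=_PALETTE[group], marker=marker, label=group, s=30,
        )
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
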