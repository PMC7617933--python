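"""Static heatmap/scatter exports for niche and proximity results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def composition_heatmap(
    composition: pd.DataFrame, path: str | Path, title: str = "Niche composition"
) -> None:
    """Niche x cell-type proportion heatmap (rows: niches, columns: types)."""
    fig, ax = plt.subplots(
        figsize=(max(6, 0.35 * composition.shape[1]), max(3, 0.4 * composition.shape[0]))
    )
    im = ax.imshow(composition.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(composition.shape[1]), composition.columns,
                  rotation=90, fontsize=7)
    ax.set_yticks(range(composition.shape[0]), composition.index, fontsize=8)
    ax.set_ylabel("niche")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="proportion")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def proximity_heatmap(z: pd.DataFrame, path: str | Path) -> None:
    """Symmetric-scale heatmap of proximity z-scores (rows: type A, cols: B)."""
    lim = float(np.nanmax(np.abs(z.to_numpy()))) or 1.0
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * z.shape[1]),) * 2)
    im = ax.imshow(z.to_numpy(), cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(z.shape[1]), z.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(z.shape[0]), z.index, fontsize=7)
    ax.set_title("Nearest-neighbour proximity z")
    fig.colorbar(im, ax=ax, label="z")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def tissue_scatter(
    cells: pd.DataFrame, color_by: str, path: str | Path, size: float = 2.0
) -> None:
    """Per-FOV scatter of cell positions coloured by a categorical column."""
    fovs = sorted(cells["fov_id"].unique())
    ncol = int(np.ceil(np.sqrt(len(fovs))))
    nrow = int(np.ceil(len(fovs) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow), squeeze=False)
    cats = sorted(cells[color_by].astype(str).unique())
    cmap = plt.get_cmap("tab20", len(cats))
    color_of = {c: cmap(i) for i, c in enumerate(cats)}
    for ax, fov in zip(axes.ravel(), fovs):
        sub = cells[cells["fov_id"] == fov]
        ax.scatter(sub["x_um"], sub["y_um"], s=size,
                   c=[color_of[str(v)] for v in sub[color_by]])
        ax.set_title(str(fov), fontsize=8)
        ax.set_aspect("equal")
    for ax in axes.ravel()[len(fovs):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
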