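"""Spatial niche detection from local cell-type neighbourhood composition.

Each cell is represented by the cell-type fractions of its k nearest
neighbours within the same field of view (self excluded, Euclidean distances
in um), and niches are k-means clusters of these composition vectors — a
composition-space analogue of the seven-niche organisation seen in inflamed
synovium, where a lining-layer band sits above compositionally distinct
sublining regions.  Gene expression enters only post hoc, through a one-sided
rank-sum test asking whether a niche's predicted pathway genes are elevated
inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

UNASSIGNED = -1


def _knn_indices(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbours per cell (positions within one FOV), self excluded.

    Ties in distance are broken by ascending cell position (input order), so
    results are independent of KD-tree internals.
    """
    pts = np.column_stack([x, y])
    n = len(pts)
    tree = cKDTree(pts)
    # query a few extra neighbours so the cut at rank k can be re-sorted
    # lexicographically by (distance, index) before truncation
    kq = min(n, k + 4)
    dist, idx = tree.query(pts, k=kq)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        order = np.lexsort((idx[i], np.round(dist[i], 9)))
        nbrs = idx[i][order]
        nbrs = nbrs[nbrs != i]
        out[i] = nbrs[:k]
    return out


def neighborhood_composition(
    cells: pd.DataFrame, k: int = 20
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cell composition of the k nearest same-FOV neighbours.

    Returns (composition frame indexed by cell_id with one column per cell
    type, rows summing to 1) and a boolean Series flagging cells in FOVs with
    fewer than k+1 cells, which receive NaN rows and stay unassigned.
    """
    types = sorted(cells["cell_type"].unique())
    type_code = pd.Categorical(cells["cell_type"], categories=types).codes
    comp = np.full((len(cells), len(types)), np.nan)
    flagged = np.zeros(len(cells), dtype=bool)
    for _, idx in cells.groupby("fov_id", sort=True).indices.items():
        idx = np.asarray(idx)
        if idx.size < k + 1:
            flagged[idx] = True
            continue
        sub = cells.iloc[idx]
        nn = _knn_indices(sub["x_um"].to_numpy(), sub["y_um"].to_numpy(), k)
        codes = type_code[idx]
        counts = np.zeros((idx.size, len(types)))
        for j in range(len(types)):
            counts[:, j] = (codes[nn] == j).sum(axis=1)
        comp[idx] = counts / k
    comp_df = pd.DataFrame(
        comp, index=pd.Index(cells["cell_id"], name="cell_id"), columns=types
    )
    return comp_df, pd.Series(flagged, index=comp_df.index, name="unassigned")


@dataclass
class NicheModel:
    """Fitted niche partition: per-cell labels plus composition summaries.

    ``labels`` uses -1 for unassigned cells; niches are numbered 0..n-1 by
    descending cell count.  ``composition`` is the row-stochastic
    niche x cell-type matrix of member cells' own types; ``centroids`` are the
    k-means centroids in neighbourhood-composition space.
    """

    labels: pd.Series
    composition: pd.DataFrame
    centroids: pd.DataFrame
    k_neighbors: int
    n_niches: int


def detect_niches(
    composition: pd.DataFrame,
    cells: pd.DataFrame,
    n_niches: int = 7,
    restarts: int = 10,
    seed: int | None = None,
    k_neighbors: int = 20,
) -> NicheModel:
    """k-means partition of neighbourhood-composition vectors into niches.

    Best of ``restarts`` seeded initializations by within-cluster sum of
    squares; niches renumbered by descending size, so labels are stable up to
    the partition itself.
    """
    valid = ~composition.isna().any(axis=1)
    X = composition.loc[valid].to_numpy()
    if n_niches > np.unique(X, axis=0).shape[0]:
        raise ValueError(
            f"n_niches={n_niches} exceeds the number of distinct composition vectors"
        )
    km = KMeans(n_clusters=n_niches, n_init=restarts, random_state=seed)
    raw = km.fit_predict(X)
    # renumber by descending cluster size (ties by original label)
    sizes = np.bincount(raw, minlength=n_niches)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(n_niches, dtype=int)
    relabel[order] = np.arange(n_niches)
    labels = np.full(len(composition), UNASSIGNED, dtype=int)
    labels[valid.to_numpy()] = relabel[raw]

    labels_s = pd.Series(labels, index=composition.index, name="niche")
    comp_matrix = _niche_type_composition(labels_s, cells)
    centroids = pd.DataFrame(
        km.cluster_centers_[order], columns=composition.columns,
        index=pd.RangeIndex(n_niches, name="niche"),
    )
    return NicheModel(
        labels=labels_s,
        composition=comp_matrix,
        centroids=centroids,
        k_neighbors=k_neighbors,
        n_niches=n_niches,
    )


def _niche_type_composition(labels: pd.Series, cells: pd.DataFrame) -> pd.DataFrame:
    merged = cells.set_index("cell_id").assign(niche=labels)
    merged = merged[merged["niche"] != UNASSIGNED]
    tab = pd.crosstab(merged["niche"], merged["cell_type"])
    return tab.div(tab.sum(axis=1), axis=0)


def niche_composition_summary(
    model: NicheModel, cells: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Niche x cell-type proportions and per-sample niche proportions.

    Both outputs are row-stochastic; a niche absent from a sample gets
    proportion 0 there.
    """
    merged = cells.set_index("cell_id").assign(niche=model.labels)
    merged = merged[merged["niche"] != UNASSIGNED]
    comp = pd.crosstab(merged["niche"], merged["cell_type"])
    comp = comp.div(comp.sum(axis=1), axis=0)
    by_sample = pd.crosstab(merged["sample_id"], merged["niche"])
    by_sample = by_sample.reindex(columns=range(model.n_niches), fill_value=0)
    by_sample = by_sample.div(by_sample.sum(axis=1), axis=0)
    return comp, by_sample


def niche_marker_enrichment(
    expr,
    labels: pd.Series,
    pathway_sets: dict[str, tuple[int, list[str]]],
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-sided rank-sum elevation of pathway genes inside their niche.

    Parameters
    ----------
    expr : AnnData
        Cells x genes counts; tested on CP10K + log1p values.
    labels
        Per-cell niche labels aligned with ``expr.obs_names``.
    pathway_sets
        pathway -> (niche label, gene list).

    Returns (per-gene frame with statistic, p, q, effect sign and tested
    flag; per-pathway frame with a ``confirmed`` column — at least one gene
    with q < 0.05 and positive effect).  Genes absent from the matrix are
    reported untested.
    """
    import scanpy as sc

    adata = expr.copy()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    X = adata.X
    lab = labels.reindex(adata.obs_names).to_numpy()

    rows = []
    for pathway, (niche, genes) in sorted(pathway_sets.items()):
        inside = lab == niche
        for gene in genes:
            if gene not in adata.var_names:
                rows.append(
                    dict(pathway=pathway, niche=niche, gene=gene,
                         stat=np.nan, p=np.nan, effect=np.nan, tested=False)
                )
                continue
            col = X[:, adata.var_names.get_loc(gene)]
            if hasattr(col, "toarray"):
                col = col.toarray()
            col = np.asarray(col).ravel()
            x_in, x_out = col[inside], col[~inside]
            stat, p = stats.mannwhitneyu(x_in, x_out, alternative="greater")
            # effect sign: AUC above/below 0.5
            effect = stat / (x_in.size * x_out.size) - 0.5
            rows.append(
                dict(pathway=pathway, niche=niche, gene=gene,
                     stat=stat, p=p, effect=effect, tested=True)
            )
    per_gene = pd.DataFrame(rows)
    tested = per_gene["tested"].to_numpy()
    q = np.full(len(per_gene), np.nan)
    if tested.any():
        q[tested] = multipletests(per_gene.loc[tested, "p"], method="fdr_bh")[1]
    per_gene["q"] = q

    confirmed = (
        per_gene[tested]
        .assign(hit=lambda d: (d["q"] < q_threshold) & (d["effect"] > 0))
        .groupby("pathway")["hit"]
        .any()
    )
    per_pathway = pd.DataFrame({"confirmed": confirmed}).reindex(
        sorted(pathway_sets), fill_value=False
    )
    return per_gene, per_pathway
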