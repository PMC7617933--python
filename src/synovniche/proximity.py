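"""Nearest-neighbour co-localization statistics with a permutation null.

For every ordered cell-type pair (A, B), the observed statistic is the
fraction of A cells whose single nearest same-FOV neighbour is of type B.
The null shuffles type labels within each FOV (positions and type counts
fixed), giving permutation moments from which a z-score is formed; the
p-value is the upper tail of the standard normal CDF of z, with
Benjamini-Hochberg correction across all reported ordered pairs.
Hierarchical clustering of the symmetrized z matrix groups co-localizing
cell types, mirroring the six proximity groups seen in multiplexed-IF
synovium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .niches import _knn_indices


def _nn_index_per_fov(cells: pd.DataFrame) -> np.ndarray:
    """Global positional index of each cell's nearest same-FOV neighbour.

    Cells in single-cell FOVs get -1 and are excluded (with a warning).
    """
    nn = np.full(len(cells), -1, dtype=np.int64)
    for fov, idx in cells.groupby("fov_id", sort=True).indices.items():
        idx = np.asarray(idx)
        if idx.size < 2:
            warnings.warn(f"FOV {fov!r} has a single cell; excluded")
            continue
        sub = cells.iloc[idx]
        local = _knn_indices(sub["x_um"].to_numpy(), sub["y_um"].to_numpy(), 1)
        nn[idx] = idx[local[:, 0]]
    return nn


def _freq_matrix(codes: np.ndarray, nn: np.ndarray, n_types: int) -> np.ndarray:
    """Row-stochastic type x type nearest-neighbour frequency matrix."""
    valid = nn >= 0
    pair = codes[valid] * n_types + codes[nn[valid]]
    counts = np.bincount(pair, minlength=n_types * n_types).reshape(
        n_types, n_types
    ).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals > 0, counts / totals, np.nan)


def nearest_neighbor_frequencies(cells: pd.DataFrame) -> pd.DataFrame:
    """Observed NN frequencies pooled over FOVs, weighted by cell counts."""
    types = sorted(cells["cell_type"].unique())
    codes = pd.Categorical(cells["cell_type"], categories=types).codes.astype(np.int64)
    nn = _nn_index_per_fov(cells)
    freq = _freq_matrix(codes, nn, len(types))
    return pd.DataFrame(freq, index=pd.Index(types, name="type_a"), columns=types)


@dataclass
class ProximityResult:
    """Ordered type-pair matrices from the permutation proximity analysis.

    All frames share index type_a / columns type_b.  Rows of ``obs_freq`` sum
    to 1; ``z`` = (obs - null_mean)/null_sd where null_sd > 0; ``p`` is the
    one-sided upper normal tail and ``q`` its BH adjustment over unmasked
    pairs.  Rows whose type has fewer than ``min_cells`` members are masked
    (NaN); degenerate pairs (null_sd == 0) carry p = 1.
    """

    obs_freq: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    z: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    degenerate: pd.DataFrame
    n_perm: int
    min_cells: int

    def tidy(self) -> pd.DataFrame:
        """Long-format table of all pairs (one row per ordered pair)."""
        frames = {
            "obs_freq": self.obs_freq, "null_mean": self.null_mean,
            "null_sd": self.null_sd, "z": self.z, "p": self.p, "q": self.q,
        }
        out = pd.concat(
            {k: v.stack(future_stack=True) for k, v in frames.items()}, axis=1
        )
        out.index.names = ["type_a", "type_b"]
        return out.reset_index()


def proximity_significance(
    cells: pd.DataFrame,
    n_perm: int = 1000,
    min_cells: int = 20,
    seed: int | None = None,
) -> ProximityResult:
    """Permutation z/p/q for every ordered cell-type pair.

    The null permutes type labels within each FOV; because positions are
    fixed, nearest-neighbour indices are computed once and each permutation
    only re-tabulates the label pairs, so large ``n_perm`` is cheap.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    types = sorted(cells["cell_type"].unique())
    n_types = len(types)
    codes = pd.Categorical(cells["cell_type"], categories=types).codes.astype(np.int64)
    nn = _nn_index_per_fov(cells)
    obs = _freq_matrix(codes, nn, n_types)

    rng = np.random.default_rng(seed)
    fov_groups = [np.asarray(ix) for _, ix in cells.groupby("fov_id", sort=True).indices.items()]
    acc = np.zeros((n_types, n_types))
    acc2 = np.zeros((n_types, n_types))
    perm_codes = codes.copy()
    for _ in range(n_perm):
        for idx in fov_groups:
            perm_codes[idx] = codes[rng.permutation(idx)]
        f = _freq_matrix(perm_codes, nn, n_types)
        acc += f
        acc2 += f * f
    null_mean = acc / n_perm
    null_var = np.maximum(acc2 / n_perm - null_mean**2, 0.0)
    null_sd = np.sqrt(null_var * n_perm / max(n_perm - 1, 1))

    degenerate = null_sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(degenerate, np.nan, (obs - null_mean) / null_sd)
    p = np.where(degenerate, 1.0, stats.norm.sf(z))

    type_counts = np.bincount(codes, minlength=n_types)
    masked_rows = type_counts < min_cells
    z[masked_rows, :] = np.nan
    p[masked_rows, :] = np.nan

    q = np.full_like(p, np.nan)
    keep = ~np.isnan(p)
    if keep.any():
        q[keep] = multipletests(p[keep], method="fdr_bh")[1]

    def _df(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=pd.Index(types, name="type_a"), columns=types)

    return ProximityResult(
        obs_freq=_df(obs), null_mean=_df(null_mean), null_sd=_df(null_sd),
        z=_df(z), p=_df(p), q=_df(q), degenerate=_df(degenerate),
        n_perm=n_perm, min_cells=min_cells,
    )


def colocalization_groups(result: ProximityResult, n_groups: int = 6) -> pd.Series:
    """Average-linkage grouping of cell types by symmetrized proximity z.

    The directional z matrix is symmetrized as (z + z')/2, converted to a
    dissimilarity d = max(S) - S, and cut into ``n_groups`` clusters.  Types
    fully masked in ``result`` are dropped before clustering.
    """
    zdf = result.z
    keep = ~zdf.isna().all(axis=1)
    types = list(zdf.index[keep])
    if n_groups > len(types):
        raise ValueError(
            f"n_groups={n_groups} exceeds {len(types)} clusterable cell types"
        )
    S = zdf.loc[types, types].to_numpy()
    S = np.nan_to_num((S + S.T) / 2.0, nan=0.0)
    d = np.max(S) - S
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=n_groups, criterion="maxclust")
    return pd.Series(labels, index=pd.Index(types, name="cell_type"), name="group")
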