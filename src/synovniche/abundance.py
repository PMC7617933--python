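"""Permutation differential cell-type abundance between two groups.

Cells are pooled across samples within each group; the statistic is the log2
fold difference of pooled proportions.  Significance comes from a cell-level
group-label permutation null (group sizes fixed) alongside a two-sided Fisher
exact test on the type-vs-rest 2x2 table, with Benjamini-Hochberg correction
over cell types.  A type is called enriched when FDR < 0.01 and
|log2FD| > 0.58 (both strict), the decision rule used for synovial
compartment comparisons.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_FDR_THRESHOLD = 0.01
DEFAULT_LFC_THRESHOLD = 0.58


def log2_fold_difference(
    count1: np.ndarray, n1: int, count2: np.ndarray, n2: int
) -> np.ndarray:
    """log2 of the ratio of pooled proportions with Haldane zero-handling.

    0.5 is added to both type counts (and 1 to both totals) only where either
    count is zero, keeping the statistic finite for near-absent populations
    without perturbing well-observed ones.
    """
    c1 = np.asarray(count1, dtype=float)
    c2 = np.asarray(count2, dtype=float)
    zero = (c1 == 0) | (c2 == 0)
    c1 = np.where(zero, c1 + 0.5, c1)
    c2 = np.where(zero, c2 + 0.5, c2)
    d1 = np.where(zero, n1 + 1.0, float(n1))
    d2 = np.where(zero, n2 + 1.0, float(n2))
    return np.log2((c1 / d1) / (c2 / d2))


def _multivariate_hypergeometric(
    colors: np.ndarray, nsample: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draws of per-type counts in a size-``nsample`` subsample.

    Sequential conditional decomposition: exactly the distribution of type
    counts in group 1 after shuffling group labels over all pooled cells.
    Returns an (n_draws, n_types) array.
    """
    colors = np.asarray(colors, dtype=np.int64)
    remaining_total = int(colors.sum())
    remaining_sample = np.full(n_draws, nsample, dtype=np.int64)
    out = np.empty((n_draws, colors.size), dtype=np.int64)
    for j, good in enumerate(colors[:-1]):
        remaining_total -= int(good)
        draw = rng.hypergeometric(good, remaining_total, remaining_sample)
        out[:, j] = draw
        remaining_sample -= draw
    out[:, -1] = remaining_sample
    return out


def permutation_proportion_test(
    counts1: pd.Series,
    counts2: pd.Series,
    n_perm: int = 10_000,
    seed: int | None = None,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Differential abundance of each cell type between two pooled groups.

    Parameters
    ----------
    counts1, counts2
        Pooled cell counts per type for group 1 / group 2.
    n_perm
        Number of label permutations for the empirical p-value.

    Returns a frame indexed by cell type with columns count_g1, count_g2,
    log2fd, p_perm, p_fisher, fdr and enriched_in.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p-value")
    types = sorted(set(counts1.index) | set(counts2.index))
    c1 = counts1.reindex(types, fill_value=0).to_numpy(dtype=np.int64)
    c2 = counts2.reindex(types, fill_value=0).to_numpy(dtype=np.int64)
    present = (c1 + c2) > 0
    if not present.all():
        dropped = [t for t, keep in zip(types, present) if not keep]
        warnings.warn(f"cell types absent from both groups dropped: {dropped}")
        types = [t for t, keep in zip(types, present) if keep]
        c1, c2 = c1[present], c2[present]
    n1, n2 = int(c1.sum()), int(c2.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must contain at least one cell")

    obs = log2_fold_difference(c1, n1, c2, n2)

    rng = np.random.default_rng(seed)
    perm_c1 = _multivariate_hypergeometric(c1 + c2, n1, n_perm, rng)
    perm_c2 = (c1 + c2)[None, :] - perm_c1
    perm_lfd = log2_fold_difference(perm_c1, n1, perm_c2, n2)
    exceed = (np.abs(perm_lfd) >= np.abs(obs)[None, :]).sum(axis=0)
    p_perm = (1.0 + exceed) / (n_perm + 1.0)

    p_fisher = np.array(
        [
            stats.fisher_exact(
                [[a, n1 - a], [b, n2 - b]], alternative="two-sided"
            ).pvalue
            for a, b in zip(c1, c2)
        ]
    )
    fdr = multipletests(p_perm, method="fdr_bh")[1]

    result = pd.DataFrame(
        {
            "count_g1": c1,
            "count_g2": c2,
            "log2fd": obs,
            "p_perm": p_perm,
            "p_fisher": p_fisher,
            "fdr": fdr,
        },
        index=pd.Index(types, name="cell_type"),
    )
    return classify_enrichment(result, fdr_threshold, lfc_threshold)


def classify_enrichment(
    results: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Label each type group1/group2/none by strict FDR and |log2FD| cuts."""
    results = results.copy()
    hit = (results["fdr"] < fdr_threshold) & (
        results["log2fd"].abs() > lfc_threshold
    )
    results["enriched_in"] = np.where(
        hit, np.where(results["log2fd"] > 0, "group1", "group2"), "none"
    )
    return results


def counts_from_cells(cells: pd.DataFrame, samples: pd.DataFrame, group: str) -> pd.Series:
    """Pool cell-type counts over all samples belonging to ``group``."""
    ids = samples.index[samples["group"] == group]
    sub = cells[cells["sample_id"].isin(ids)]
    return sub["cell_type"].value_counts()
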