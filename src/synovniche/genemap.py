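"""Mapping gene lists onto cell states by average normalized expression.

Average expression is defined as CP10K + log1p (counts scaled to 10,000 per
cell, then log(1 + x)) averaged within each state — the de facto single-cell
convention, recorded in output metadata.  Severity-associated genes are
summarized by their 5 highest-expressing states and GWAS loci by their top 3;
gene-set overlap uses a one-sided Fisher exact test filtered at P < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scanpy as sc
from scipy import stats

NORMALIZATION = "cp10k_log1p"
LOW_CONFIDENCE_MIN_CELLS = 10


@dataclass
class StateExpression:
    """Cell-state x gene matrix of average normalized expression."""

    means: pd.DataFrame
    n_cells: pd.Series
    normalization: str = NORMALIZATION

    @property
    def low_confidence(self) -> pd.Series:
        return self.n_cells < LOW_CONFIDENCE_MIN_CELLS


def average_expression_by_state(expr, labels: pd.Series) -> StateExpression:
    """CP10K+log1p expression averaged within each cell state.

    ``labels`` is aligned to ``expr.obs_names``; empty states are dropped
    with a warning and states with fewer than 10 cells flagged
    low-confidence.
    """
    adata = expr.copy()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    lab = pd.Series(labels).reindex(adata.obs_names)
    if lab.isna().any():
        warnings.warn(f"{int(lab.isna().sum())} cells without a state label dropped")
    states = sorted(lab.dropna().unique())
    X = adata.X
    rows, counts = [], []
    for state in states:
        mask = (lab == state).to_numpy()
        sub = X[mask]
        mean = np.asarray(sub.mean(axis=0)).ravel()
        rows.append(mean)
        counts.append(int(mask.sum()))
    means = pd.DataFrame(
        rows, index=pd.Index(states, name="state"), columns=adata.var_names
    )
    return StateExpression(means=means, n_cells=pd.Series(counts, index=means.index))


def top_expressing_states(
    state_expr: StateExpression, genes: list[str], top_n: int = 5
) -> pd.DataFrame:
    """Per-gene ordered list of the highest-expressing states.

    States are sorted by average expression descending with ties broken by
    state name; genes absent from the matrix are reported with an empty list
    and present=False.
    """
    rows = []
    means = state_expr.means
    for gene in genes:
        if gene not in means.columns:
            rows.append({"gene": gene, "present": False, "top_states": []})
            continue
        col = means[gene]
        order = sorted(col.index, key=lambda s: (-col[s], s))
        rows.append({"gene": gene, "present": True, "top_states": order[:top_n]})
    return pd.DataFrame(rows).set_index("gene")


def gene_set_enrichment_fisher(
    module_genes: set[str] | list[str],
    set_genes: set[str] | list[str],
    universe: set[str] | list[str],
    alpha: float = 0.05,
) -> dict:
    """One-sided Fisher exact test of gene-set overlap within a universe.

    The 2x2 table cross-classifies universe genes by (in set) x (in module);
    the alternative is over-representation ("greater").  Returns odds ratio,
    p and the ``significant`` flag at p < alpha.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    module = set(module_genes)
    gset = set(set_genes)
    if not module <= universe:
        raise ValueError("module_genes must be a subset of the universe")
    if not gset <= universe:
        raise ValueError("set_genes must be a subset of the universe")
    a = len(module & gset)
    b = len(gset - module)
    c = len(module - gset)
    d = len(universe) - a - b - c
    res = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return {
        "odds_ratio": res.statistic,
        "p": res.pvalue,
        "overlap": a,
        "significant": bool(res.pvalue < alpha),
    }
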