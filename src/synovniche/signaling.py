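"""Simplified ligand-receptor interactome scoring between cell states.

Interaction strength for (sender s, receiver t, ligand L, receptor R) is the
product of the min-max-scaled state-mean expression of L in s and R in t —
a closed-form stand-in for mass-action communication scores that preserves
ranking semantics.  Significance comes from shuffling cell-state labels and
recomputing the strength (unadjusted P < 0.05 convention); pathway-level
aggregation sums strengths over a pathway's pairs, and within-niche
restriction keeps only sender/receiver states that each hold at least a
minimum share of the niche's cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse

from .genemap import LOW_CONFIDENCE_MIN_CELLS

DEFAULT_MEMBERSHIP_MIN = 0.02
STRENGTH_FORMULA = "minmax_scaled_state_mean_product"


def validate_lr_database(db: pd.DataFrame) -> pd.DataFrame:
    """Check the (ligand, receptor, pathway) table invariants."""
    required = {"ligand", "receptor", "pathway"}
    missing = required - set(db.columns)
    if missing:
        raise ValueError(f"LR database missing columns: {sorted(missing)}")
    if db.duplicated(["ligand", "receptor"]).any():
        raise ValueError("duplicate (ligand, receptor) rows in LR database")
    if db["pathway"].isna().any() or (db["pathway"] == "").any():
        raise ValueError("pathway names must be non-empty")
    return db


def _state_means(X, codes: np.ndarray, n_states: int) -> np.ndarray:
    """states x genes mean matrix via one-hot product (permutation-friendly)."""
    ind = sparse.csr_matrix(
        (np.ones(codes.size), (codes, np.arange(codes.size))),
        shape=(n_states, codes.size),
    )
    sums = ind @ X
    if sparse.issparse(sums):
        sums = sums.toarray()
    sums = np.asarray(sums)
    counts = np.bincount(codes, minlength=n_states).astype(float)
    return sums / counts[:, None]


def _minmax_scale(means: np.ndarray) -> np.ndarray:
    lo = means.min(axis=0)
    hi = means.max(axis=0)
    rng = np.where(hi > lo, hi - lo, 1.0)
    return (means - lo) / rng


def lr_interaction_strength(
    expr,
    labels: pd.Series,
    db: pd.DataFrame,
    n_perm: int = 100,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every sender x receiver x (ligand, receptor) combination.

    Expression is CP10K+log1p normalized, averaged per state, and each
    gene's state means are min-max scaled to [0, 1]; a strength is therefore
    exactly 0 when either gene's scaled mean is 0 in the respective state.
    ``p_perm`` comes from ``n_perm`` shuffles of the cell-state labels, with
    the add-one estimator p = (1 + #{strength* >= obs}) / (n_perm + 1); the
    ``significant`` flag applies the unadjusted P < alpha convention.
    Pairs whose ligand or receptor is absent are skipped with a warning.
    """
    db = validate_lr_database(db)
    adata = expr.copy()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)

    lab = pd.Series(labels).reindex(adata.obs_names)
    states = sorted(lab.dropna().unique())
    codes = pd.Categorical(lab, categories=states).codes.astype(np.int64)
    n_states = len(states)
    n_cells_per_state = np.bincount(codes, minlength=n_states)
    low_conf = {
        s: int(n) < LOW_CONFIDENCE_MIN_CELLS
        for s, n in zip(states, n_cells_per_state)
    }

    present = db["ligand"].isin(adata.var_names) & db["receptor"].isin(adata.var_names)
    if not present.all():
        warnings.warn(
            f"{int((~present).sum())} LR pairs skipped (gene absent from matrix)"
        )
    db_used = db[present].reset_index(drop=True)
    genes = sorted(set(db_used["ligand"]) | set(db_used["receptor"]))
    gene_idx = {g: i for i, g in enumerate(genes)}
    X = adata[:, genes].X
    if sparse.issparse(X):
        X = X.tocsc()

    def strengths(c: np.ndarray) -> np.ndarray:
        scaled = _minmax_scale(_state_means(X, c, n_states))
        lig = scaled[:, [gene_idx[g] for g in db_used["ligand"]]]
        rec = scaled[:, [gene_idx[g] for g in db_used["receptor"]]]
        # (sender, receiver, pair) strength tensor
        return lig[:, None, :] * rec[None, :, :]

    obs = strengths(codes)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        exceed += strengths(rng.permutation(codes)) >= obs
    p_perm = (1.0 + exceed) / (n_perm + 1.0)

    s_idx, t_idx, k_idx = np.meshgrid(
        np.arange(n_states), np.arange(n_states), np.arange(len(db_used)),
        indexing="ij",
    )
    out = pd.DataFrame(
        {
            "sender": np.asarray(states, dtype=object)[s_idx.ravel()],
            "receiver": np.asarray(states, dtype=object)[t_idx.ravel()],
            "ligand": db_used["ligand"].to_numpy()[k_idx.ravel()],
            "receptor": db_used["receptor"].to_numpy()[k_idx.ravel()],
            "pathway": db_used["pathway"].to_numpy()[k_idx.ravel()],
            "strength": obs.ravel(),
            "p_perm": p_perm.ravel(),
        }
    )
    out["significant"] = out["p_perm"] < alpha
    out["low_confidence"] = (
        out["sender"].map(low_conf) | out["receiver"].map(low_conf)
    )
    return out


def aggregate_pathways(
    scores: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pathway x (sender, receiver) strength sums plus per-state totals.

    ``outgoing(s)`` sums strengths sent by s and ``incoming(t)`` those
    received by t, so the two columns have equal grand totals.
    """
    pathway_matrix = (
        scores.pivot_table(
            index="pathway", columns=["sender", "receiver"],
            values="strength", aggfunc="sum", fill_value=0.0,
        )
    )
    outgoing = scores.groupby("sender")["strength"].sum()
    incoming = scores.groupby("receiver")["strength"].sum()
    states = sorted(set(outgoing.index) | set(incoming.index))
    totals = pd.DataFrame(
        {
            "outgoing": outgoing.reindex(states, fill_value=0.0),
            "incoming": incoming.reindex(states, fill_value=0.0),
        },
        index=pd.Index(states, name="state"),
    )
    return pathway_matrix, totals


def restrict_to_niche(
    scores: pd.DataFrame,
    niche_composition: pd.DataFrame,
    membership_min: float = DEFAULT_MEMBERSHIP_MIN,
) -> dict[int, pd.DataFrame]:
    """Keep, per niche, only interactions between states resident in it.

    ``niche_composition`` is the row-stochastic niche x cell-state matrix; a
    state is resident in a niche when it holds at least ``membership_min`` of
    the niche's cells, and an interaction survives when both its sender and
    receiver are resident.
    """
    out: dict[int, pd.DataFrame] = {}
    for niche, row in niche_composition.iterrows():
        resident = set(row.index[row >= membership_min])
        kept = scores[
            scores["sender"].isin(resident) & scores["receiver"].isin(resident)
        ].reset_index(drop=True)
        out[niche] = kept
    return out


def niche_pathway_summary(
    per_niche: dict[int, pd.DataFrame], top_n: int = 5
) -> pd.DataFrame:
    """Top pathways per niche by summed surviving strength."""
    rows = []
    for niche, scores in per_niche.items():
        top = (
            scores.groupby("pathway")["strength"].sum()
            .sort_values(ascending=False)
            .head(top_n)
        )
        for rank, (pathway, strength) in enumerate(top.items(), start=1):
            rows.append(
                dict(niche=niche, rank=rank, pathway=pathway, strength=strength)
            )
    return pd.DataFrame(rows)
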