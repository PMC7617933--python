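"""Seeded end-to-end benchmarks on planted-truth synthetic tissue.

Each function builds a synthetic dataset with a known signal (or a known
null), runs the corresponding pipeline stage, and returns the recovery or
calibration measure.  The problem sizes are desk-scale versions of the study
conditions: 20,000 cells / 16 FOVs for niche recovery, 2,000 cells per group
for abundance, 8 samples for severity links.  Brute-force statistical oracles
(exhaustive hypergeometric Fisher p, textbook step-up BH) live here too so
equivalence of the fast implementations can be checked end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from . import abundance, annotate, association, niches, proximity, signaling, simulate


# ---------------------------------------------------------------------------
# brute-force oracles


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums the probabilities of every 2x2 table with the same margins whose
    point probability does not exceed the observed one (with a tiny relative
    tolerance for float ties, the standard convention).
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def fisher_one_sided_oracle(table) -> float:
    """One-sided (greater) Fisher p: upper hypergeometric tail."""
    (a, b), (c, d) = table
    n = a + b + c + d
    return float(stats.hypergeom.sf(a - 1, n, a + c, a + b))


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def enumerate_fisher_tables(max_margin: int = 30):
    """Yield every 2x2 count table with all four margins <= max_margin."""
    for r1 in range(max_margin + 1):
        for r2 in range(max_margin + 1):
            n = r1 + r2
            if n == 0:
                continue
            for c1 in range(max(0, n - max_margin), min(n, max_margin) + 1):
                for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
                    yield (a, r1 - a), (c1 - a, n - r1 - c1 + a)


def fisher_oracle_max_error(max_margin: int = 30) -> float:
    """Max |scipy two-sided Fisher p - enumeration oracle| over all tables.

    The two-sided p is invariant under row swap, column swap and transpose,
    so only one representative per symmetry orbit is evaluated.
    """
    seen: set[tuple[int, int, int, int]] = set()
    err = 0.0
    for (a, b), (c, d) in enumerate_fisher_tables(max_margin):
        orbit = [
            (a, b, c, d), (c, d, a, b), (b, a, d, c), (d, c, b, a),
            (a, c, b, d), (b, d, a, c), (c, a, d, b), (d, b, c, a),
        ]
        key = min(orbit)
        if key in seen:
            continue
        seen.add(key)
        table = ((a, b), (c, d))
        p_impl = stats.fisher_exact(table, alternative="two-sided").pvalue
        err = max(err, abs(p_impl - fisher_two_sided_oracle(table)))
    return err


def bh_oracle_max_error(n_vectors: int = 1000, seed: int = 0) -> float:
    """Max |statsmodels BH - step-up oracle| over random p-vectors (n <= 50)."""
    rng = np.random.default_rng(seed)
    err = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 51))
        p = rng.random(n)
        impl = multipletests(p, method="fdr_bh")[1]
        err = max(err, float(np.max(np.abs(impl - bh_oracle(p)))))
    return err


# ---------------------------------------------------------------------------
# niche recovery


def niche_recovery_ari(
    seed: int, n_cells: int = 20_000, n_types: int = 30, k: int = 20,
    n_niches: int = 7,
) -> float:
    """ARI between planted and detected niches on bands tissue."""
    config = simulate.default_tissue_config(
        n_cells=n_cells, seed=seed, n_types=n_types, n_niches=n_niches
    )
    cells = simulate.generate_tissue(config)
    comp, _ = niches.neighborhood_composition(cells, k=k)
    model = niches.detect_niches(comp, cells, n_niches=n_niches, seed=seed)
    mask = model.labels.to_numpy() != niches.UNASSIGNED
    return float(
        adjusted_rand_score(
            cells["niche_true"].to_numpy()[mask], model.labels.to_numpy()[mask]
        )
    )


# ---------------------------------------------------------------------------
# proximity


def _iid_tissue(seed: int, n_cells: int, n_types: int = 8) -> pd.DataFrame:
    types = [f"t{j}" for j in range(n_types)]
    config = simulate.TissueConfig(
        n_cells=n_cells,
        composition=np.full((1, n_types), 1.0 / n_types),
        cell_types=types,
        n_niches=1,
        niche_layout="bands",
        fov_grid=(2, 2),
        fov_size_um=400.0,
        seed=seed,
    )
    return simulate.generate_tissue(config)


def proximity_calibration(
    seed: int, n_cells: int = 5000, n_perm: int = 500
) -> tuple[float, float, int]:
    """(mean z, fraction of pairs with q <= 0.05, number of pairs) under iid labels."""
    cells = _iid_tissue(seed, n_cells)
    res = proximity.proximity_significance(cells, n_perm=n_perm, seed=seed + 1)
    z = res.z.to_numpy()
    q = res.q.to_numpy()
    keep = ~np.isnan(z)
    return float(np.nanmean(z)), float((q[keep] <= 0.05).mean()), int(keep.sum())


def proximity_power(
    seed: int, n_cells: int = 4000, n_perm: int = 1000, doublet_frac: float = 0.2
) -> bool:
    """True when planted A-B doublets give z(A->B) > 3 and q < 0.05."""
    n_types = 6
    types = [f"t{j}" for j in range(n_types)]
    config = simulate.TissueConfig(
        n_cells=n_cells,
        composition=np.full((1, n_types), 1.0 / n_types),
        cell_types=types,
        n_niches=1,
        fov_grid=(2, 2),
        fov_size_um=400.0,
        doublet_pairs=[("t0", "t1", doublet_frac)],
        seed=seed,
    )
    cells = simulate.generate_tissue(config)
    res = proximity.proximity_significance(cells, n_perm=n_perm, seed=seed + 1)
    return bool(res.z.loc["t0", "t1"] > 3 and res.q.loc["t0", "t1"] < 0.05)


def proximity_power_rate(n_seeds: int = 20, base_seed: int = 0) -> float:
    hits = sum(proximity_power(base_seed + 1000 * s) for s in range(n_seeds))
    return hits / n_seeds


# ---------------------------------------------------------------------------
# abundance


def _two_group_counts(
    seed: int, p_a1: float, p_a2: float, n_per_group: int = 2000, n_types: int = 8
) -> tuple[pd.Series, pd.Series]:
    rng = np.random.default_rng(seed)
    types = ["typeA"] + [f"other{j}" for j in range(n_types - 1)]
    p1 = np.r_[p_a1, np.full(n_types - 1, (1 - p_a1) / (n_types - 1))]
    p2 = np.r_[p_a2, np.full(n_types - 1, (1 - p_a2) / (n_types - 1))]
    c1 = pd.Series(rng.multinomial(n_per_group, p1), index=types)
    c2 = pd.Series(rng.multinomial(n_per_group, p2), index=types)
    return c1, c2


def abundance_power_rate(
    n_seeds: int = 50, n_perm: int = 10_000, base_seed: int = 0
) -> float:
    """Fraction of seeds flagging the planted 0.30-vs-0.10 type."""
    hits = 0
    for s in range(n_seeds):
        c1, c2 = _two_group_counts(base_seed + 7 * s, 0.30, 0.10)
        res = abundance.permutation_proportion_test(
            c1, c2, n_perm=n_perm, seed=base_seed + 7 * s + 1
        )
        hits += res.loc["typeA", "enriched_in"] != "none"
    return hits / n_seeds


def abundance_null_flag_rate(
    n_seeds: int = 200, n_perm: int = 10_000, base_seed: int = 0
) -> float:
    """Per-type flag rate when both groups share the same proportions."""
    flags = total = 0
    for s in range(n_seeds):
        c1, c2 = _two_group_counts(base_seed + 11 * s, 0.2, 0.2)
        res = abundance.permutation_proportion_test(
            c1, c2, n_perm=n_perm, seed=base_seed + 11 * s + 1
        )
        flags += int((res["enriched_in"] != "none").sum())
        total += len(res)
    return flags / total


# ---------------------------------------------------------------------------
# annotation


def annotation_accuracy(
    snr: float, seed: int = 0, cells_per_type: int = 200
) -> float:
    """Argmax annotation accuracy on the 21-marker / 12-type panel."""
    panel = simulate.default_if_panel()
    types = list(panel.index)
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(cells_per_type * len(types))],
            "cell_type": np.repeat(types, cells_per_type),
        }
    )
    intensities = simulate.generate_if_intensities(
        cells, panel, snr=snr, seed=seed
    )
    scores = annotate.score_signatures(intensities, panel)
    assigned = annotate.assign_cell_types(scores)
    return float((assigned["cell_type"].to_numpy() == cells["cell_type"].to_numpy()).mean())


# ---------------------------------------------------------------------------
# correlation gate + severity


def correlation_gate_rates(
    n_seeds: int = 200, n: int = 50, base_seed: int = 0
) -> tuple[float, float]:
    """(Pearson rate on Gaussian data, Spearman rate on log-normal data)."""
    rng = np.random.default_rng(base_seed)
    pearson = spearman = 0
    for _ in range(n_seeds):
        x, y = rng.normal(size=n), rng.normal(size=n)
        if association.choose_correlation(x, y).method == "pearson":
            pearson += 1
        x = np.exp(rng.normal(0, 1.5, size=n))
        y = np.exp(rng.normal(0, 1.5, size=n))
        if association.choose_correlation(x, y).method == "spearman":
            spearman += 1
    return pearson / n_seeds, spearman / n_seeds


def severity_sign_recovery(
    seed: int, n_samples: int = 8, pos_niche: str = "plasma_cell",
    neg_niche: str = "sublining_stroma",
) -> bool:
    """True when planted +/- niche-severity links come back with right signs."""
    cats = [pos_niche, neg_niche, "lining_layer", "myeloid_lymphoid", "vascular"]
    props = pd.DataFrame(
        [[0.20, 0.25, 0.20, 0.20, 0.15]], index=["JIA"], columns=cats
    )
    config = simulate.CohortConfig(
        n_samples_per_group=n_samples,
        true_proportions=props,
        cells_per_sample_range=(400, 800),
        severity_link={pos_niche: 15.0, neg_niche: -15.0},
        severity_noise_sd=0.2,
        seed=seed,
    )
    cohort = simulate.generate_cohort_counts(config)
    res = association.niche_severity_correlation(
        cohort.proportions, cohort.samples["severity"]
    )
    return bool(res.loc[pos_niche, "sign"] == 1 and res.loc[neg_niche, "sign"] == -1)


def severity_sign_recovery_rate(n_seeds: int = 50, base_seed: int = 0) -> float:
    return sum(severity_sign_recovery(base_seed + 13 * s) for s in range(n_seeds)) / n_seeds


# ---------------------------------------------------------------------------
# signaling


def _signaling_dataset(seed: int, planted: bool, n_cells: int = 600):
    types = ["A", "B", "C"]
    rng = np.random.default_rng(seed)
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "cell_type": rng.choice(types, size=n_cells),
        }
    )
    db, overrides = simulate.generate_lr_truth(
        10, ("L1", "R1", "A", "B") if planted else None, types, seed=seed
    )
    genes = sorted(set(db["ligand"]) | set(db["receptor"]))
    markers = pd.DataFrame(0.1, index=types, columns=genes + [f"HK_{t}" for t in types])
    for t in types:
        markers.loc[t, f"HK_{t}"] = 5.0  # housekeeping anchor per type
    for (ctype, gene), mean in overrides.items():
        markers.loc[ctype, gene] = mean
    expr_config = simulate.ExpressionConfig(
        markers=markers, baseline_mean=0.05, dispersion=10.0,
        library_size_range=(900, 1100), seed=seed + 1,
    )
    adata = simulate.generate_expression(cells, expr_config)
    labels = pd.Series(cells["cell_type"].to_numpy(), index=cells["cell_id"].to_numpy())
    return adata, labels, db


def signaling_top_rank(seed: int, n_perm: int = 100) -> bool:
    """True when the planted (A,B,L1,R1) interaction is the global maximum."""
    adata, labels, db = _signaling_dataset(seed, planted=True)
    scores = signaling.lr_interaction_strength(
        adata, labels, db, n_perm=n_perm, seed=seed + 2
    )
    top = scores.loc[scores["strength"].idxmax()]
    return bool(
        (top["sender"], top["receiver"], top["ligand"], top["receptor"])
        == ("A", "B", "L1", "R1")
    )


def signaling_top_rank_rate(n_seeds: int = 10, base_seed: int = 0) -> float:
    return sum(signaling_top_rank(base_seed + 17 * s) for s in range(n_seeds)) / n_seeds


def signaling_null_significant_rate(seed: int = 0, n_perm: int = 100) -> tuple[float, int]:
    """(fraction of scores with p_perm < 0.05, number of scores) with no signal."""
    adata, labels, db = _signaling_dataset(seed, planted=False)
    scores = signaling.lr_interaction_strength(
        adata, labels, db, n_perm=n_perm, seed=seed + 2
    )
    return float(scores["significant"].mean()), len(scores)


# ---------------------------------------------------------------------------
# niche pathway confirmation


def _pathway_dataset(seed: int, n_cells: int = 4000, n_niches: int = 5):
    """Bands tissue with niche-exclusive types and 15 pathway gene sets, 12 elevated."""
    types = [f"T{j}" for j in range(n_niches)]
    config = simulate.TissueConfig(
        n_cells=n_cells,
        composition=np.eye(n_niches),
        cell_types=types,
        n_niches=n_niches,
        niche_layout="bands",
        fov_grid=(2, 2),
        fov_size_um=400.0,
        seed=seed,
    )
    cells = simulate.generate_tissue(config)

    pathway_sets: dict[str, tuple[int, list[str]]] = {}
    all_genes = []
    elevated_truth = {}
    for i in range(15):
        niche = i % n_niches
        gset = [f"P{i:02d}G{j}" for j in range(2)]
        pathway_sets[f"pathway{i:02d}"] = (niche, gset)
        elevated_truth[f"pathway{i:02d}"] = i < 12
        all_genes.extend(gset)
    # filler marker genes equalize each type's total high-expression mass, so
    # relative (CP10K) expression of non-elevated genes is flat across niches
    filler = [f"FILL_{t}_{j}" for t in types for j in range(2)]
    markers = pd.DataFrame(
        0.1, index=types, columns=all_genes + filler + [f"HK_{t}" for t in types]
    )
    for t in types:
        markers.loc[t, f"HK_{t}"] = 5.0
    elevated_per_type = {t: 0 for t in types}
    for i in range(12):  # truly elevated pathways
        niche, gset = pathway_sets[f"pathway{i:02d}"]
        for g in gset:
            markers.loc[types[niche], g] = 4.0
        elevated_per_type[types[niche]] += len(gset)
    max_elev = max(elevated_per_type.values())
    for t in types:
        for j in range(max_elev - elevated_per_type[t]):
            markers.loc[t, f"FILL_{t}_{j}"] = 4.0
    expr_config = simulate.ExpressionConfig(
        markers=markers, baseline_mean=0.05, dispersion=10.0,
        library_size_range=(900, 1100), seed=seed + 1,
    )
    adata = simulate.generate_expression(cells, expr_config)
    labels = pd.Series(cells["niche_true"].to_numpy(), index=cells["cell_id"].to_numpy())
    return adata, labels, pathway_sets, elevated_truth


def niche_pathway_confirmation(seed: int) -> int:
    """Number of the 15 planted pathway sets confirmed in their niche."""
    adata, labels, pathway_sets, _ = _pathway_dataset(seed)
    _, per_pathway = niches.niche_marker_enrichment(adata, labels, pathway_sets)
    return int(per_pathway["confirmed"].sum())


def niche_pathway_null_rate(seed: int, n_label_perms: int = 4) -> float:
    """Per-pathway confirmation rate after permuting niche labels."""
    adata, labels, pathway_sets, _ = _pathway_dataset(seed)
    rng = np.random.default_rng(seed + 5)
    confirmed = total = 0
    for _ in range(n_label_perms):
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        _, per_pathway = niches.niche_marker_enrichment(adata, perm, pathway_sets)
        confirmed += int(per_pathway["confirmed"].sum())
        total += len(per_pathway)
    return confirmed / total
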