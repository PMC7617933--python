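"""Synthetic synovial tissue generator with planted ground truth.

Emulates the data modalities of a multiplexed synovium study: spatial cell
maps organised into compositional niches (a lining-layer band facing the
synovial cavity plus sublining niches), sparse gene counts with cell-state
marker structure, multiplexed-IF marker intensities, cohort cell-count tables
with group structure, and Krenn-scale severity scores linearly linked to
planted niche proportions.  Every generator is deterministic given its seed
and returns the planted truth alongside the data, so each downstream
statistic can be tested for recovery of a known signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


# ---------------------------------------------------------------------------
# configs


@dataclass
class TissueConfig:
    """Layout and composition of a simulated tissue map.

    ``composition`` is a niche x cell-type row-stochastic matrix; ``bands``
    stacks horizontal strata with niche 0 at the top edge (the lining layer
    facing the synthetic cavity), ``blobs`` scatters Gaussian-disc niches,
    ``mixed`` keeps niche 0 as the top band and places the rest as blobs.
    ``doublet_pairs`` plants (typeA, typeB, fraction) contact pairs: the given
    fraction of type-A cells gets a type-B partner moved to within 1 um.
    """

    n_cells: int
    composition: np.ndarray
    cell_types: list[str]
    n_niches: int = 7
    niche_layout: str = "bands"
    fov_grid: tuple[int, int] = (4, 4)
    fov_size_um: float = 500.0
    doublet_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.composition = np.asarray(self.composition, dtype=float)
        if self.composition.ndim != 2:
            raise ConfigError("composition must be a 2-D niche x type matrix")
        if self.composition.shape[0] != self.n_niches:
            raise ConfigError(
                f"n_niches={self.n_niches} but composition has "
                f"{self.composition.shape[0]} rows"
            )
        if self.composition.shape[1] != len(self.cell_types):
            raise ConfigError("composition columns must match cell_types")
        if np.any(self.composition < 0):
            raise ConfigError("composition entries must be non-negative")
        rowsums = self.composition.sum(axis=1)
        if np.any(rowsums == 0):
            raise ConfigError("composition row with zero mass")
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ConfigError("composition rows must sum to 1 within 1e-9")
        if self.niche_layout not in ("bands", "blobs", "mixed"):
            raise ConfigError(f"unknown niche_layout {self.niche_layout!r}")
        for a, b, frac in self.doublet_pairs:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"doublet fraction {frac} outside [0, 1]")
            for t in (a, b):
                if t not in self.cell_types:
                    raise ConfigError(f"doublet type {t!r} not in cell_types")


@dataclass
class ExpressionConfig:
    """Marker-gene means per cell type for the count generator.

    ``markers`` is a cell-type x gene table of negative-binomial means; genes
    absent from the table default to ``baseline_mean`` in every type.  Counts
    follow a gamma-Poisson mixture with shape ``dispersion`` (Poisson limit as
    dispersion grows) and per-cell library sizes uniform in
    ``library_size_range``.
    """

    markers: pd.DataFrame
    baseline_mean: float = 0.1
    dispersion: float = 10.0
    library_size_range: tuple[float, float] = (800.0, 1200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        lo, hi = self.library_size_range
        if lo > hi or lo <= 0:
            raise ConfigError("library_size_range must satisfy 0 < min <= max")
        above = (self.markers.to_numpy() > self.baseline_mean).any(axis=1)
        if not above.all():
            bad = list(self.markers.index[~above])
            raise ConfigError(
                f"cell types without any marker above baseline: {bad}"
            )


@dataclass
class CohortConfig:
    """Per-group composition truth for cohort count tables.

    ``true_proportions`` is a group x category row-stochastic frame (categories
    may be cell types or niches).  Per-sample severity is
    ``clamp(baseline + sum(coef * realized proportion) + noise, 0, 3)`` on the
    Krenn inflammatory-infiltrate sub-score scale, using ``severity_link``
    coefficients keyed by category.
    """

    n_samples_per_group: int
    true_proportions: pd.DataFrame
    cells_per_sample_range: tuple[int, int] = (500, 1500)
    severity_link: dict[str, float] = field(default_factory=dict)
    severity_noise_sd: float = 0.2
    severity_baseline: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1:
            raise ConfigError("empty group: n_samples_per_group must be >= 1")
        props = self.true_proportions.to_numpy(dtype=float)
        if np.any(props < 0) or np.any(np.abs(props.sum(axis=1) - 1) > 1e-9):
            raise ConfigError("true_proportions rows must sum to 1 within 1e-9")
        if self.severity_noise_sd < 0:
            raise ConfigError("severity_noise_sd must be >= 0")
        lo, hi = self.cells_per_sample_range
        if lo > hi or lo < 1:
            raise ConfigError("cells_per_sample_range must satisfy 1 <= min <= max")
        unknown = set(self.severity_link) - set(self.true_proportions.columns)
        if unknown:
            raise ConfigError(f"severity_link keys not in proportions: {sorted(unknown)}")

    @property
    def groups(self) -> list[str]:
        return list(self.true_proportions.index)


# ---------------------------------------------------------------------------
# tissue geometry


def _niche_of_positions(
    x: np.ndarray, y: np.ndarray, layout: str, n_niches: int,
    fov_size: float, rng: np.random.Generator,
) -> np.ndarray:
    """Niche index per cell within one FOV; niche 0 hugs the top edge."""
    if layout == "bands" or n_niches == 1:
        # stratum 0 at y = fov_size (the cavity-facing lining layer)
        band = np.floor((fov_size - y) / fov_size * n_niches).astype(int)
        return np.clip(band, 0, n_niches - 1)
    if layout == "blobs":
        centers = rng.uniform(0, fov_size, size=(n_niches, 2))
        d2 = (x[:, None] - centers[:, 0]) ** 2 + (y[:, None] - centers[:, 1]) ** 2
        return np.argmin(d2, axis=1)
    # mixed: top band is niche 0, remaining area split among blob niches
    band_depth = fov_size / n_niches
    niche = np.zeros(x.size, dtype=int)
    below = y < fov_size - band_depth
    if n_niches > 1 and below.any():
        centers = rng.uniform(0, fov_size, size=(n_niches - 1, 2))
        d2 = (
            (x[below, None] - centers[:, 0]) ** 2
            + (y[below, None] - centers[:, 1]) ** 2
        )
        niche[below] = 1 + np.argmin(d2, axis=1)
    return niche


def generate_tissue(config: TissueConfig) -> pd.DataFrame:
    """Simulate a cell table over a FOV grid with planted niche structure.

    Returns a frame with columns cell_id, sample_id, fov_id, x_um, y_um,
    cell_type and niche_true.  Coordinates are continuous um with the origin
    at each FOV's lower-left corner; all downstream spatial statistics are
    FOV-local, so FOVs are generated independently.
    """
    rng = np.random.default_rng(config.seed)
    n_fov = config.fov_grid[0] * config.fov_grid[1]
    per_fov = rng.multinomial(config.n_cells, np.full(n_fov, 1.0 / n_fov))
    types = np.asarray(config.cell_types, dtype=object)

    frames = []
    offset = 0
    for f in range(n_fov):
        n = per_fov[f]
        x = rng.uniform(0, config.fov_size_um, size=n)
        y = rng.uniform(0, config.fov_size_um, size=n)
        niche = _niche_of_positions(
            x, y, config.niche_layout, config.n_niches, config.fov_size_um, rng
        )
        # cell type drawn from the niche's composition row
        u = rng.random(n)
        cum = np.cumsum(config.composition, axis=1)
        tidx = (u[:, None] > cum[niche]).sum(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"c{offset + i:06d}" for i in range(n)],
                    "sample_id": "sim",
                    "fov_id": f"fov{f:03d}",
                    "x_um": x,
                    "y_um": y,
                    "cell_type": types[tidx],
                    "niche_true": niche,
                }
            )
        )
        offset += n
    cells = pd.concat(frames, ignore_index=True)

    for type_a, type_b, frac in config.doublet_pairs:
        _plant_doublets(cells, type_a, type_b, frac, config.fov_size_um, rng)
    return cells


def _plant_doublets(
    cells: pd.DataFrame, type_a: str, type_b: str, frac: float,
    fov_size: float, rng: np.random.Generator,
) -> None:
    """Relocate type-B cells to within 1 um of a chosen fraction of type-A cells."""
    for _, idx in cells.groupby("fov_id", sort=True).indices.items():
        sub = cells.iloc[idx]
        a_idx = np.asarray(idx)[(sub["cell_type"] == type_a).to_numpy()]
        b_idx = np.asarray(idx)[(sub["cell_type"] == type_b).to_numpy()]
        n_pairs = min(int(round(frac * a_idx.size)), b_idx.size)
        if n_pairs == 0:
            continue
        chosen_a = rng.choice(a_idx, size=n_pairs, replace=False)
        chosen_b = rng.choice(b_idx, size=n_pairs, replace=False)
        r = rng.uniform(0.1, 1.0, size=n_pairs)
        theta = rng.uniform(0, 2 * np.pi, size=n_pairs)
        ax = cells["x_um"].to_numpy()[chosen_a]
        ay = cells["y_um"].to_numpy()[chosen_a]
        bx = np.clip(ax + r * np.cos(theta), 0, fov_size)
        by = np.clip(ay + r * np.sin(theta), 0, fov_size)
        cells.iloc[chosen_b, cells.columns.get_loc("x_um")] = bx
        cells.iloc[chosen_b, cells.columns.get_loc("y_um")] = by


# ---------------------------------------------------------------------------
# expression


def generate_expression(cells: pd.DataFrame, config: ExpressionConfig) -> AnnData:
    """Draw sparse gamma-Poisson counts per cell from its type's marker means.

    Per-gene means are the type's marker row (baseline for unlisted genes),
    rescaled per cell so expected totals match a uniform library size, then
    passed through a gamma multiplier with shape = dispersion and unit mean.
    """
    rng = np.random.default_rng(config.seed)
    types = config.markers.index
    unknown = set(cells["cell_type"]) - set(types)
    if unknown:
        raise ConfigError(f"cell types missing from markers table: {sorted(unknown)}")

    genes = list(config.markers.columns)
    means = config.markers.to_numpy(dtype=float)
    type_code = pd.Categorical(cells["cell_type"], categories=types).codes
    cell_means = means[type_code]  # cells x genes

    lo, hi = config.library_size_range
    lib = rng.uniform(lo, hi, size=len(cells))
    totals = cell_means.sum(axis=1)
    lam = cell_means * (lib / totals)[:, None]
    gamma_mult = rng.gamma(config.dispersion, 1.0 / config.dispersion, size=lam.shape)
    counts = rng.poisson(lam * gamma_mult)

    adata = AnnData(
        X=sparse.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame(
            {"cell_type": cells["cell_type"].to_numpy()},
            index=cells["cell_id"].to_numpy(),
        ),
        var=pd.DataFrame(index=genes),
    )
    return adata


# ---------------------------------------------------------------------------
# multiplexed-IF intensities


def default_if_panel() -> pd.DataFrame:
    """A 21-marker, 12-type signature table echoing a synovial IF panel.

    Rows are cell types found in inflamed synovium (lining fibroblasts,
    sublining stroma, vascular and lymphatic endothelium, myeloid and lymphoid
    states, mast cells); columns are nuclear/cytoplasmic markers.  Values are
    expected mean intensities in arbitrary units; every row is distinct.
    """
    markers = [
        "DAPI", "CD45", "CD3", "CD4", "CD8", "CD20", "CD138", "CD68", "CD14",
        "S100A8", "SPP1", "LYVE1", "MCT", "CD31", "CD146", "SMA", "PDPN",
        "PRG4", "CD90", "HLA-DR", "CLU",
    ]
    base = {
        "T cell": dict(DAPI=8, CD45=9, CD3=9, CD4=6, CD8=5),
        "B cell": dict(DAPI=8, CD45=9, CD20=9, **{"HLA-DR": 6}),
        "Plasma cell": dict(DAPI=8, CD45=5, CD138=9, CLU=2),
        "S100A8+ monocyte": dict(DAPI=8, CD45=8, CD14=7, S100A8=9, **{"HLA-DR": 5}),
        "SPP1+ macrophage": dict(DAPI=8, CD45=7, CD68=9, SPP1=9, **{"HLA-DR": 6}),
        "LYVE1+ macrophage": dict(DAPI=8, CD45=7, CD68=8, LYVE1=9, CD14=4),
        "Mast cell": dict(DAPI=8, CD45=6, MCT=9),
        "Lining fibroblast": dict(DAPI=8, PDPN=9, PRG4=9, CLU=5, CD90=2),
        "Sublining fibroblast": dict(DAPI=8, PDPN=6, CD90=9, CLU=3),
        "CD146-hi vessel": dict(DAPI=8, CD31=9, CD146=9, SMA=3),
        "SMA-hi vessel": dict(DAPI=8, CD31=8, SMA=9, CD146=4),
        "Lymphatic": dict(DAPI=8, CD31=7, LYVE1=8, PDPN=7),
    }
    table = pd.DataFrame(0.5, index=list(base), columns=markers, dtype=float)
    for ctype, vals in base.items():
        for marker, v in vals.items():
            table.loc[ctype, marker] = float(v)
    return table


def generate_if_intensities(
    cells: pd.DataFrame,
    signatures: pd.DataFrame,
    snr: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell marker intensities: signature row plus Gaussian noise.

    Noise sd per marker is its signature dynamic range (max - min across
    types) divided by ``snr``; intensities are clamped at 0.
    """
    if snr <= 0:
        raise ConfigError("snr must be > 0")
    missing = set(cells["cell_type"]) - set(signatures.index)
    if missing:
        raise ConfigError(f"signatures missing cell types: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    sig = signatures.to_numpy(dtype=float)
    code = pd.Categorical(cells["cell_type"], categories=signatures.index).codes
    clean = sig[code]
    sd = (sig.max(axis=0) - sig.min(axis=0)) / snr
    noisy = np.clip(clean + rng.normal(0, 1, size=clean.shape) * sd, 0, None)
    return pd.DataFrame(
        noisy, index=cells["cell_id"].to_numpy(), columns=signatures.columns
    )


# ---------------------------------------------------------------------------
# cohort counts + severity


@dataclass
class CohortCounts:
    """Samples x category count table with per-sample group and severity."""

    counts: pd.DataFrame
    samples: pd.DataFrame  # index sample_id; columns group, severity

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)


def generate_cohort_counts(config: CohortConfig) -> CohortCounts:
    """Multinomial per-sample counts from each group's true proportions.

    Severity is a clamped linear function of each sample's *realized*
    category proportions, so planted niche-severity correlations survive
    sampling noise by construction.
    """
    rng = np.random.default_rng(config.seed)
    cats = list(config.true_proportions.columns)
    lo, hi = config.cells_per_sample_range
    rows, meta = [], []
    for group in config.groups:
        p = config.true_proportions.loc[group].to_numpy(dtype=float)
        for i in range(config.n_samples_per_group):
            n = int(rng.integers(lo, hi + 1))
            counts = rng.multinomial(n, p)
            props = counts / n
            sev = config.severity_baseline + sum(
                coef * props[cats.index(cat)]
                for cat, coef in config.severity_link.items()
            )
            sev += rng.normal(0, config.severity_noise_sd)
            rows.append(counts)
            meta.append(
                {
                    "sample_id": f"{group}_s{i:02d}",
                    "group": group,
                    "severity": float(np.clip(sev, 0.0, 3.0)),
                }
            )
    samples = pd.DataFrame(meta).set_index("sample_id")
    counts = pd.DataFrame(rows, index=samples.index, columns=cats)
    return CohortCounts(counts=counts, samples=samples)


# ---------------------------------------------------------------------------
# ligand-receptor truth


_PATHWAYS = ["COLLAGEN", "CXCL", "CCL", "MIF", "APP", "MHC-II", "SELL", "VEGF"]


def generate_lr_truth(
    n_pairs: int,
    planted: tuple[str, str, str, str] | None,
    cell_types: list[str],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Emit a ligand-receptor pair list plus marker overrides planting a signal.

    ``planted`` is (ligand, receptor, sender_type, receiver_type) or None for
    a pure noise-floor database.  Returns (pair table with pathway labels,
    overrides mapping (cell_type, gene) -> mean) to feed ExpressionConfig
    markers.  Decoy genes stay at baseline in every type.
    """
    if planted is not None:
        _, _, sender, receiver = planted
        for t in (sender, receiver):
            if t not in cell_types:
                raise ConfigError(f"planted type {t!r} not in cell_types")
    records = []
    overrides: dict[tuple[str, str], float] = {}
    start = 0
    if planted is not None:
        lig, rec, sender, receiver = planted
        records.append({"ligand": lig, "receptor": rec, "pathway": _PATHWAYS[0]})
        overrides[(sender, lig)] = 25.0
        overrides[(receiver, rec)] = 25.0
        start = 1
    for i in range(start, n_pairs):
        records.append(
            {
                "ligand": f"LIG{i:02d}",
                "receptor": f"REC{i:02d}",
                "pathway": _PATHWAYS[i % len(_PATHWAYS)],
            }
        )
    return pd.DataFrame(records), overrides


# ---------------------------------------------------------------------------
# default study-scale scenario


def default_tissue_config(
    n_cells: int = 20_000, seed: int = 0, n_types: int = 30, n_niches: int = 7
) -> TissueConfig:
    """A 7-niche, multi-type bands tissue over a 4x4 FOV grid.

    Scales the study geometry (hundreds of thousands of cells over hundreds of
    FOVs) down to a desk-size 20,000 cells / 16 FOVs while keeping the layered
    lining-layer-over-sublining organisation.  Each niche is dominated by a
    disjoint block of cell types with a diffuse shared background, so planted
    labels are recoverable but not trivially separable.
    """
    rng = np.random.default_rng(seed)
    types = [f"state{j:02d}" for j in range(n_types)]
    comp = np.full((n_niches, n_types), 0.2 / n_types)
    blocks = np.array_split(np.arange(n_types), n_niches)
    for i, block in enumerate(blocks):
        comp[i, block] += 0.8 / len(block) + rng.uniform(0, 0.02, size=len(block))
    comp /= comp.sum(axis=1, keepdims=True)
    return TissueConfig(
        n_cells=n_cells,
        composition=comp,
        cell_types=types,
        n_niches=n_niches,
        niche_layout="bands",
        fov_grid=(4, 4),
        fov_size_um=500.0,
        seed=seed,
    )
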