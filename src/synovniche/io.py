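"""Readers and writers for the pipeline's plain-text formats.

Cell tables, intensities, cohort counts and LR pair lists travel as UTF-8
comma-separated CSV with a header row; sparse counts as a Matrix Market trio
(matrix.mtx, features.tsv, barcodes.tsv); gene sets as standard GMT.  Every
command writes a JSON metadata sidecar recording version, seed, config and
input checksums so re-runs are verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

CELL_TABLE_COLUMNS = ["cell_id", "sample_id", "fov_id", "x_um", "y_um", "cell_type"]


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell spatial table CSV."""
    df = pd.read_csv(path)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table missing required columns: {missing}")
    for col in ("x_um", "y_um"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric {col} at row {row}")
        df[col] = pd.to_numeric(df[col])
    if df["cell_id"].duplicated().any():
        dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].unique()[:5]
        raise ValueError(f"duplicate cell_id values: {list(dupes)}")
    return df


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def read_counts(directory: str | Path) -> ad.AnnData:
    """Read a cells x genes Matrix Market trio into AnnData.

    Expects matrix.mtx (cells x genes), features.tsv (genes) and
    barcodes.tsv (cells); rejects negative or non-integer entries and
    dimension mismatches.
    """
    directory = Path(directory)
    mat = scipy_io.mmread(directory / "matrix.mtx").tocsr()
    genes = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0]
    if mat.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix is {mat.shape} but labels imply {(len(cells), len(genes))}"
        )
    if mat.data.size and (mat.data < 0).any():
        raise ValueError("counts must be non-negative")
    if mat.data.size and np.any(mat.data != np.round(mat.data)):
        raise ValueError("counts must be integers")
    return ad.AnnData(
        X=mat.astype(np.int64),
        obs=pd.DataFrame(index=cells.astype(str)),
        var=pd.DataFrame(index=genes.astype(str)),
    )


def write_counts(adata: ad.AnnData, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    scipy_io.mmwrite(directory / "matrix.mtx", X.tocoo())
    pd.Series(adata.var_names).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into {set name: gene list}.

    Lines are name <tab> description <tab> gene...; lines with fewer than 3
    fields raise with their line number, duplicate set names are rejected and
    duplicate genes within a set deduplicated with a warning.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
            name, _desc, *genes = fields
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r} (line {lineno})")
            deduped = list(dict.fromkeys(g for g in genes if g))
            if len(deduped) < len([g for g in genes if g]):
                warnings.warn(f"duplicate genes in set {name!r} deduplicated")
            sets[name] = deduped
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_metadata_sidecar(
    out_path: str | Path,
    command: str,
    seed: int | None,
    config: dict,
    inputs: list[str | Path] = (),
) -> None:
    """Write <out_path>.meta.json recording the run's provenance."""
    from . import __version__

    meta = {
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
        "input_checksums": {
            str(p): _checksum(Path(p)) for p in inputs if Path(p).exists()
        },
    }
    Path(str(out_path) + ".meta.json").write_text(
        json.dumps(meta, indent=2, default=str)
    )
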