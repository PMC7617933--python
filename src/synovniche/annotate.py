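"""Cell-type annotation from mean marker fluorescence.

Segmented cells are scored against a cell-type x marker signature table by
cosine similarity after identical per-marker scaling of data and signatures
(z-score by default, matching relative-average-expression displays of IF
panels).  Assignment is deterministic argmax with an optional confidence
margin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import cosine_similarity

UNASSIGNED = "unassigned"


def _scale(
    data: pd.DataFrame, signatures: pd.DataFrame, scaling: str
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a per-marker affine transform to data and signatures alike.

    Parameters are fitted on the pooled rows of data and signatures, so the
    transform is identical for both by construction, well defined even for a
    single cell, and a cell identical to a signature row stays identical
    after scaling.
    """
    X = data.to_numpy(dtype=float)
    S = signatures.to_numpy(dtype=float)
    pool = np.vstack([X, S])
    if scaling == "zscore":
        mu = pool.mean(axis=0)
        sd = pool.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return (X - mu) / sd, (S - mu) / sd
    if scaling == "minmax":
        lo, hi = pool.min(axis=0), pool.max(axis=0)
        rng = np.where(hi > lo, hi - lo, 1.0)
        return (X - lo) / rng, (S - lo) / rng
    raise ValueError(f"unknown scaling {scaling!r}")


def score_signatures(
    intensities: pd.DataFrame,
    signatures: pd.DataFrame,
    scaling: str = "zscore",
) -> pd.DataFrame:
    """Cosine-similarity score of every cell against every signature row.

    Marker columns of ``intensities`` must cover the signature panel; the
    per-marker scaling parameters are fitted on the data and applied
    identically to the signature rows, so scores are invariant to per-marker
    affine rescaling of the raw measurements.
    """
    missing = [m for m in signatures.columns if m not in intensities.columns]
    if missing:
        raise ValueError(f"markers missing from intensity table: {missing}")
    data = intensities[signatures.columns]
    if (data.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    X, S = _scale(data, signatures, scaling)
    scores = cosine_similarity(X, S)
    return pd.DataFrame(scores, index=intensities.index, columns=signatures.index)


def assign_cell_types(scores: pd.DataFrame, margin_min: float = 0.0) -> pd.DataFrame:
    """Argmax assignment with alphabetical tie-break and a confidence margin.

    Cells whose top-minus-second score margin is below ``margin_min`` are
    labelled "unassigned".  Returns a frame with cell_type, score and margin.
    """
    ordered = scores[sorted(scores.columns)]
    A = ordered.to_numpy(dtype=float)
    if not np.isfinite(A).all():
        raise ValueError("scores must be finite")
    best = A.argmax(axis=1)  # first max -> alphabetically first type
    top = A[np.arange(len(A)), best]
    A2 = A.copy()
    A2[np.arange(len(A)), best] = -np.inf
    second = A2.max(axis=1) if A.shape[1] > 1 else np.full(len(A), -np.inf)
    margin = top - second
    labels = np.asarray(ordered.columns, dtype=object)[best]
    labels = np.where(margin < margin_min, UNASSIGNED, labels)
    return pd.DataFrame(
        {"cell_type": labels, "score": top, "margin": margin}, index=scores.index
    )
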