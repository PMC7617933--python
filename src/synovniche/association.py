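"""Normality-gated correlation analyses.

Each correlation first runs a Shapiro-Wilk normality test on both vectors:
Pearson is used only when both pass (p >= alpha), otherwise Spearman with
average ranks for ties — the gate used for compartment-proportion and
niche-severity correlations.  Flagging follows the reporting convention
|r| > 0.5 with unadjusted P < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA_NORM = 0.05
FLAG_R = 0.5
FLAG_P = 0.05


@dataclass
class CorrelationResult:
    """A single gated correlation between two vectors."""

    pair: tuple[str, str]
    method: str  # pearson | spearman | undefined
    r: float
    p: float
    n: int
    shapiro_p_x: float
    shapiro_p_y: float

    @property
    def flagged(self) -> bool:
        return (
            np.isfinite(self.r)
            and abs(self.r) > FLAG_R
            and self.p < FLAG_P
        )


def choose_correlation(
    x: np.ndarray,
    y: np.ndarray,
    alpha_norm: float = DEFAULT_ALPHA_NORM,
    pair: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Pearson iff both vectors pass Shapiro-Wilk at ``alpha_norm``, else Spearman.

    Requires n >= 5 finite observations; a constant vector yields an
    undefined correlation (r = NaN) rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(pair, "undefined", np.nan, np.nan, len(x),
                                 np.nan, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns for n > 5000
        sw_x = stats.shapiro(x).pvalue
        sw_y = stats.shapiro(y).pvalue
    if sw_x >= alpha_norm and sw_y >= alpha_norm:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(pair, method, float(r), float(p), len(x),
                             float(sw_x), float(sw_y))


def cross_compartment_correlation(
    props_a: pd.DataFrame,
    props_b: pd.DataFrame,
    alpha_norm: float = DEFAULT_ALPHA_NORM,
) -> pd.DataFrame:
    """Per-cell-type gated correlation of proportions between two compartments.

    Rows are matched on sample id; unmatched samples are dropped with a
    warning.  Flags follow |r| > 0.5 and unadjusted p < 0.05.
    """
    shared = props_a.index.intersection(props_b.index)
    if len(shared) < len(props_a) or len(shared) < len(props_b):
        warnings.warn("unmatched samples dropped from cross-compartment correlation")
    if len(shared) < 5:
        raise ValueError("need at least 5 matched sample pairs")
    rows = []
    for ctype in props_a.columns.intersection(props_b.columns):
        res = choose_correlation(
            props_a.loc[shared, ctype].to_numpy(),
            props_b.loc[shared, ctype].to_numpy(),
            alpha_norm=alpha_norm,
            pair=(str(ctype), str(ctype)),
        )
        rows.append(
            dict(cell_type=ctype, method=res.method, r=res.r, p=res.p,
                 n=res.n, flagged=res.flagged)
        )
    return pd.DataFrame(rows).set_index("cell_type")


def niche_severity_correlation(
    niche_by_sample: pd.DataFrame,
    severity: pd.Series,
    alpha_norm: float = DEFAULT_ALPHA_NORM,
) -> pd.DataFrame:
    """Gated correlation of each niche's per-sample proportion with severity.

    Severity is a per-sample score on the Krenn infiltrate 0-3 scale; an
    all-equal severity vector yields undefined correlations for every niche.
    Signs are reported so positive (inflammatory-niche) and negative
    (stromal-niche) associations can be read off directly.
    """
    shared = niche_by_sample.index.intersection(severity.index)
    sev = severity.loc[shared].to_numpy(dtype=float)
    rows = []
    for niche in niche_by_sample.columns:
        res = choose_correlation(
            niche_by_sample.loc[shared, niche].to_numpy(), sev,
            alpha_norm=alpha_norm, pair=(str(niche), "severity"),
        )
        sign = 0 if not np.isfinite(res.r) or res.r == 0 else int(np.sign(res.r))
        rows.append(
            dict(niche=niche, method=res.method, r=res.r, p=res.p, n=res.n,
                 sign=sign, flagged=res.flagged)
        )
    return pd.DataFrame(rows).set_index("niche")
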