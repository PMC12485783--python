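"""Promoter methylation / expression integration.

Pairs the two omics layers gene-by-gene, classifies genes into the five
effect-size quadrant categories (Hyper-Up, Hyper-Down, Hypo-Up, Hypo-Down,
Low-effect), and applies the inverse-correlation filter that defines
epigenetically controlled genes: DEG and promoter DMG with opposite
directions, Pearson r <= -0.6 with p < 0.1 across the paired samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QUADRANTS",
    "align_layers",
    "gene_correlation",
    "quadrant_classify",
    "integration_table",
    "epigenetic_control_filter",
    "dmg_deg_venn",
]

QUADRANTS = ("Hyper-Up", "Hyper-Down", "Hypo-Up", "Hypo-Down", "Low-effect")


def align_layers(expr: pd.DataFrame, meth: pd.DataFrame,
                 gene_map: Optional[Mapping[str, str]] = None
                 ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both layers to common genes and samples, complete cases only.

    ``gene_map`` translates methylation row ids (promoter region ids) to
    gene names; identity when omitted. Output row and column order is
    identical across the two returned matrices.
    """
    if gene_map is not None:
        meth = meth.rename(index=dict(gene_map))
        meth = meth[~meth.index.duplicated(keep="first")]
    genes = expr.index.intersection(meth.index)
    samples = expr.columns.intersection(meth.columns)
    if len(genes) == 0 or len(samples) == 0:
        raise ValueError("no overlap between expression and methylation layers")
    e = expr.loc[genes, samples]
    m = meth.loc[genes, samples]
    complete = e.notna().all(axis=1) & m.notna().all(axis=1)
    e, m = e.loc[complete], m.loc[complete]
    if e.empty:
        raise ValueError("no complete-case gene remains after alignment")
    return e, m


def gene_correlation(meth_row: Sequence[float],
                     expr_row: Sequence[float]) -> Tuple[float, float]:
    """Pearson r between paired methylation and expression values and its
    two-sided p-value (t on n-2 degrees of freedom; |r| = 1 maps to p = 0)."""
    x = np.asarray(meth_row, dtype=float)
    y = np.asarray(expr_row, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) >= 1.0 - 1e-15:
        return float(np.sign(r)), 0.0
    return r, float(res.pvalue)


def quadrant_classify(expr_log2fc: float, meth_log2quot: float,
                      expr_cut: float = 1.0, meth_cut: float = 0.1) -> str:
    """Five-category effect-size quadrant."""
    if not (np.isfinite(expr_log2fc) and np.isfinite(meth_log2quot)):
        raise ValueError("effect sizes must be finite")
    if abs(expr_log2fc) < expr_cut or abs(meth_log2quot) < meth_cut:
        return "Low-effect"
    meth_dir = "Hyper" if meth_log2quot > 0 else "Hypo"
    expr_dir = "Up" if expr_log2fc > 0 else "Down"
    return f"{meth_dir}-{expr_dir}"


def integration_table(expr: pd.DataFrame, meth: pd.DataFrame,
                      deg_table: pd.DataFrame, meth_table: pd.DataFrame,
                      gene_map: Optional[Mapping[str, str]] = None,
                      expr_cut: float = 1.0, meth_cut: float = 0.1
                      ) -> pd.DataFrame:
    """Build per-gene integration records.

    ``expr``/``meth`` carry the per-sample values entering the correlation
    (typically TMM log2 CPM and promoter-mean betas of the treated arm).
    ``deg_table`` must carry log2fc / q_value / is_deg / direction (indexed
    by gene); ``meth_table`` must carry mean_quot_log2 / delta_beta /
    p_value / direction indexed like ``meth`` (region ids resolved through
    ``gene_map``).
    """
    e, m = align_layers(expr, meth, gene_map=gene_map)
    mt = meth_table.copy()
    if gene_map is not None:
        mt = mt.rename(index=dict(gene_map))
        mt = mt[~mt.index.duplicated(keep="first")]
    rows = []
    for gene in e.index:
        if gene not in deg_table.index or gene not in mt.index:
            continue
        try:
            r, p = gene_correlation(m.loc[gene].values, e.loc[gene].values)
        except ValueError:
            warnings.warn(f"gene {gene}: degenerate correlation; excluded")
            continue
        expr_lfc = float(deg_table.loc[gene, "log2fc"])
        meth_quot = float(mt.loc[gene, "mean_quot_log2"])
        rows.append({
            "gene": gene,
            "expr_log2fc": expr_lfc,
            "meth_log2quot": meth_quot,
            "pearson_r": r,
            "pearson_p": p,
            "quadrant": quadrant_classify(expr_lfc, meth_quot,
                                          expr_cut=expr_cut, meth_cut=meth_cut),
            "is_deg": bool(deg_table.loc[gene, "is_deg"]),
            "deg_direction": str(deg_table.loc[gene, "direction"]),
            "meth_p": float(mt.loc[gene, "p_value"]),
            "meth_delta_beta": float(mt.loc[gene, "delta_beta"]),
            "meth_direction": str(mt.loc[gene, "direction"]),
        })
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()


def epigenetic_control_filter(records: pd.DataFrame, r_cut: float = -0.6,
                              p_cut: float = 0.1,
                              dmg_p_threshold: float = 0.05,
                              dmg_delta_threshold: float = 0.20) -> pd.DataFrame:
    """Apply the inverse-correlation filter to an integration table.

    A gene passes iff it is a DEG, its promoter is differentially
    methylated (p below ``dmg_p_threshold`` and |delta-beta| >=
    ``dmg_delta_threshold``) in the opposite direction, and the per-sample
    Pearson correlation satisfies r <= ``r_cut`` with p < ``p_cut``.
    ``filter_class`` is ``activated`` for hypo-up genes, ``repressed`` for
    hyper-down genes, ``none`` otherwise.
    """
    out = records.copy()
    if out.empty:
        out["passes_epigenetic_filter"] = pd.Series(dtype=bool)
        out["filter_class"] = pd.Series(dtype=object)
        return out
    is_dmg = ((out["meth_p"] < dmg_p_threshold)
              & (out["meth_delta_beta"].abs() >= dmg_delta_threshold))
    discordant = (
        ((out["deg_direction"] == "up") & (out["meth_direction"] == "hypo"))
        | ((out["deg_direction"] == "down") & (out["meth_direction"] == "hyper"))
    )
    passes = (out["is_deg"] & is_dmg & discordant
              & (out["pearson_r"] <= r_cut) & (out["pearson_p"] < p_cut))
    out["passes_epigenetic_filter"] = passes
    out["filter_class"] = "none"
    out.loc[passes & (out["deg_direction"] == "up"), "filter_class"] = "activated"
    out.loc[passes & (out["deg_direction"] == "down"), "filter_class"] = "repressed"
    return out


def dmg_deg_venn(dmg_genes: Sequence[str],
                 deg_genes: Sequence[str]) -> Tuple[int, int, int]:
    """(n_dmg_only, n_deg_only, n_both) set-overlap counts."""
    dmg, deg = set(dmg_genes), set(deg_genes)
    both = dmg & deg
    return len(dmg - deg), len(deg - dmg), len(both)
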