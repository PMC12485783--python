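"""Gene-set module scores (per-sample mean of per-gene z-scores),
marker-signature cell-population scores, and the two-group comparisons
applied to them (exact Wilcoxon rank-sum at small n, Welch's t otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .expression_stats import bh_adjust

__all__ = [
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "gene_zscores",
    "module_score",
    "module_score_table",
    "signature_scores",
    "wilcoxon_rank_sum",
    "welch_ttest",
    "compare_groups_table",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


def read_gmt(path) -> List[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, _desc, *members = fields
            members = tuple(g for g in members if g)
            sets.append(GeneSet(name, members))
    return sets


def write_gmt(path, gene_sets: Iterable[GeneSet]) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "na", *gs.members]) + "\n")


def gene_zscores(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across samples (sample sd, ddof=1).

    Zero-variance genes map to all-zero rows rather than being dropped, so
    set membership stays stable.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scores need >= 2 samples")
    mean = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    z = expr.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def module_score(z: pd.DataFrame, gs: GeneSet) -> pd.Series:
    """Per-sample mean z-score over the set's members present in the matrix."""
    present = [g for g in gs.members if g in z.index]
    if not present:
        raise ValueError(f"no member of {gs.name!r} present in the matrix")
    return z.loc[present].mean(axis=0).rename(gs.name)


def module_score_table(expr: pd.DataFrame,
                       gene_sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Samples x gene-sets table of mean z-scores."""
    z = gene_zscores(expr)
    return pd.concat([module_score(z, gs) for gs in gene_sets], axis=1)


def signature_scores(expr_log2: pd.DataFrame,
                     marker_sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Marker-mean abundance scores: populations x samples.

    ``expr_log2`` must already be on a log2 scale (e.g. TMM log2 CPM).
    Populations with no marker present in the matrix are excluded with a
    warning.
    """
    rows = {}
    for gs in marker_sets:
        present = [g for g in gs.members if g in expr_log2.index]
        if not present:
            warnings.warn(f"population {gs.name!r}: no marker present; skipped")
            continue
        rows[gs.name] = expr_log2.loc[present].mean(axis=0)
    if not rows:
        raise ValueError("no population had any marker present")
    return pd.DataFrame(rows).T


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float],
                      exact_max_n: int = 8) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U statistic, p-value).

    The exact null distribution is used when both groups have at most
    ``exact_max_n`` observations and there are no ties; otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs >= 1 observation")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied across both groups; p = 1")
        return float(a.size * b.size / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= exact_max_n and b.size <= exact_max_n
                         and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Welch's t-test with documented zero-variance edge cases."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero variance with unequal means; p = 0")
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_groups_table(scores: pd.DataFrame, groups: Sequence[str],
                         test: str = "wilcoxon") -> pd.DataFrame:
    """Row-wise two-group comparison of a populations/sets x samples table,
    with BH adjustment across rows and median-difference effect sizes."""
    groups = pd.Series(list(groups), index=scores.columns)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two group levels required")
    ga = scores.loc[:, groups == levels[0]]
    gb = scores.loc[:, groups == levels[1]]
    testfun = {"wilcoxon": wilcoxon_rank_sum, "welch": welch_ttest}[test]
    stats_p = [testfun(ga.loc[i].values, gb.loc[i].values) for i in scores.index]
    out = pd.DataFrame({
        "statistic": [s for s, _ in stats_p],
        "p_value": [p for _, p in stats_p],
        "median_diff": (ga.median(axis=1) - gb.median(axis=1)),
    }, index=scores.index)
    out["q_value"] = bh_adjust(out["p_value"].values)
    return out
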