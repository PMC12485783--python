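"""Methylation-side analysis: beta/M-value handling, differential
methylation calling (|delta-beta| >= 0.2 and p < 0.05 by default, Welch t
on M-values), aggregation of probes to genomic feature classes, region
log2 quotients, and hyper/hypo direction counting.

No multiple-testing adjustment is applied at the site level by default
(the operative rule is a raw p threshold); BH-adjusted q-values are
reported alongside for optional use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .expression_stats import bh_adjust

__all__ = [
    "FEATURE_CLASSES",
    "ProbeAnnotation",
    "m_values",
    "dms_test",
    "call_dms",
    "aggregate_regions",
    "region_log2_quotient",
    "count_dms_directions",
]

FEATURE_CLASSES = ("tiling", "genes", "promoters", "cpg_islands")


@dataclass
class ProbeAnnotation:
    """Probe coordinates plus feature-class memberships.

    ``memberships[feature_class][region_id]`` is the list of member probes.
    Coordinates are 0-based half-open internally (BED convention).
    """

    probe_positions: pd.DataFrame  # index=probe, columns: contig, start, end
    memberships: Dict[str, Dict[str, List[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fc, regions in self.memberships.items():
            if fc not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {fc!r}")
            for rid, probes in regions.items():
                if not probes:
                    raise ValueError(f"region {rid!r} has no probes")

    def regions(self, feature_class: str) -> Dict[str, List[str]]:
        if feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {feature_class!r}")
        return self.memberships.get(feature_class, {})


def _check_beta(beta: pd.DataFrame) -> None:
    vals = beta.values
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("beta values must lie in [0, 1]")


def m_values(beta: pd.DataFrame, clip: float = 0.01) -> pd.DataFrame:
    """M = log2(beta / (1 - beta)) with betas clipped to [clip, 1-clip]."""
    if not 0 < clip < 0.5:
        raise ValueError("clip must lie in (0, 0.5)")
    _check_beta(beta)
    b = beta.clip(lower=clip, upper=1 - clip)
    return np.log2(b / (1 - b))


def dms_test(beta: pd.DataFrame, groups: Sequence[str],
             group_a: Optional[str] = None, group_b: Optional[str] = None,
             clip: float = 0.01) -> pd.DataFrame:
    """Per-row differential methylation: delta-beta on the beta scale, p
    from a two-sided Welch t-test on M-values.

    Rows may be probes or aggregated regions. Direction is ``hyper`` when
    group A exceeds group B.
    """
    _check_beta(beta)
    groups = pd.Series(list(groups), index=beta.columns)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two group levels required")
    if group_a is None:
        group_a, group_b = levels[0], levels[1]
    cols_a = groups[groups == group_a].index
    cols_b = groups[groups == group_b].index
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 samples")

    mvals = m_values(beta, clip=clip)
    xa, xb = mvals[cols_a].values, mvals[cols_b].values
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate rows handled below
        t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    both_flat = (va == 0) & (vb == 0)
    equal_means = np.isclose(xa.mean(axis=1), xb.mean(axis=1))
    p = np.where(both_flat & equal_means, 1.0, p)
    p = np.where(both_flat & ~equal_means, 0.0, p)
    if np.any(both_flat & ~equal_means):
        warnings.warn("zero variance with unequal means in some rows; p = 0")
    p = np.where(np.isfinite(p), p, 1.0)

    delta = beta[cols_a].mean(axis=1).values - beta[cols_b].mean(axis=1).values
    return pd.DataFrame({
        "delta_beta": delta,
        "p_value": p,
        "q_value": bh_adjust(p),
        "direction": np.where(delta >= 0, "hyper", "hypo"),
    }, index=beta.index)


def call_dms(records: pd.DataFrame, delta_threshold: float = 0.20,
             p_threshold: float = 0.05, use_q: bool = False) -> pd.DataFrame:
    """Flag DMSs at |delta-beta| >= 0.2 and p < 0.05 (defaults)."""
    out = records.copy()
    pcol = "q_value" if use_q else "p_value"
    out["is_dms"] = ((out["delta_beta"].abs() >= delta_threshold)
                     & (out[pcol] < p_threshold))
    return out


def aggregate_regions(beta: pd.DataFrame, ann: ProbeAnnotation,
                      feature_class: str, min_probes: int = 1) -> pd.DataFrame:
    """Region-level beta matrix: unweighted mean of member-probe betas."""
    _check_beta(beta)
    regions = ann.regions(feature_class)
    rows = {}
    for rid in sorted(regions):
        probes = [p for p in regions[rid] if p in beta.index]
        if len(probes) < min_probes:
            continue
        rows[rid] = beta.loc[probes].mean(axis=0)
    return pd.DataFrame(rows).T if rows else pd.DataFrame(columns=beta.columns)


def region_log2_quotient(region_beta: pd.DataFrame, groups: Sequence[str],
                         epsilon: float = 0.01,
                         group_a: Optional[str] = None,
                         group_b: Optional[str] = None) -> pd.DataFrame:
    """Per-region log2((mean_A + eps) / (mean_B + eps)) plus the Welch p
    on M-values — the region-level record the integration stage consumes."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    base = dms_test(region_beta, groups, group_a=group_a, group_b=group_b)
    groups = pd.Series(list(groups), index=region_beta.columns)
    levels = pd.unique(groups)
    if group_a is None:
        group_a, group_b = levels[0], levels[1]
    mean_a = region_beta.loc[:, groups == group_a].mean(axis=1)
    mean_b = region_beta.loc[:, groups == group_b].mean(axis=1)
    out = pd.DataFrame({
        "mean_beta_a": mean_a,
        "mean_beta_b": mean_b,
        "mean_quot_log2": np.log2((mean_a + epsilon) / (mean_b + epsilon)),
        "delta_beta": base["delta_beta"],
        "p_value": base["p_value"],
        "direction": base["direction"],
    }, index=region_beta.index)
    return out


def count_dms_directions(records: pd.DataFrame) -> Tuple[int, int]:
    """(n_hyper, n_hypo) among records flagged ``is_dms``."""
    if "is_dms" not in records.columns:
        raise ValueError("records must carry is_dms (run call_dms first)")
    if records.empty:
        return 0, 0
    hits = records[records["is_dms"]]
    n_hyper = int((hits["direction"] == "hyper").sum())
    n_hypo = int((hits["direction"] == "hypo").sum())
    return n_hyper, n_hypo
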