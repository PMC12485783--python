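"""Synthetic probe annotation: probe coordinates plus memberships in the
four genomic feature classes (5,000-bp tiling bins, gene bodies, promoters,
CpG islands).

Layout: probe ``p<i>`` sits at position ``100 + 30*i`` on the synthetic
contig. Gene ``g<i>`` (i < n_genes) owns probe ``p<i>`` as its single
promoter probe and as its gene-body probe; probes beyond ``n_genes`` are
intergenic and grouped pairwise into CpG islands. All probes fall into
tiling bins by position.
"""

from __future__ import annotations

from typing import Dict, List

import pandas as pd

from ..methylation_analysis import ProbeAnnotation
from .config import SyntheticConfig
from .genome import DEFAULT_CONTIG

__all__ = ["gene_names", "probe_names", "build_probe_annotation",
           "promoter_gene_map"]

_PROBE_START = 100
_PROBE_STEP = 30
_TILE_BP = 5000


def gene_names(n: int) -> List[str]:
    return [f"g{i:04d}" for i in range(n)]


def probe_names(n: int) -> List[str]:
    return [f"p{i:04d}" for i in range(n)]


def build_probe_annotation(cfg: SyntheticConfig) -> ProbeAnnotation:
    if cfg.n_probes < cfg.n_genes:
        raise ValueError("need at least one probe per gene (n_probes >= n_genes)")
    probes = probe_names(cfg.n_probes)
    genes = gene_names(cfg.n_genes)
    positions = pd.DataFrame({
        "contig": DEFAULT_CONTIG,
        "start": [_PROBE_START + _PROBE_STEP * i for i in range(cfg.n_probes)],
    }, index=pd.Index(probes, name="probe"))
    positions["end"] = positions["start"] + 1

    memberships: Dict[str, Dict[str, List[str]]] = {
        "promoters": {f"prom_{g}": [probes[i]] for i, g in enumerate(genes)},
        "genes": {f"body_{g}": [probes[i]] for i, g in enumerate(genes)},
        "tiling": {},
        "cpg_islands": {},
    }
    for i, p in enumerate(probes):
        tile = f"tile_{(positions['start'].iloc[i]) // _TILE_BP:04d}"
        memberships["tiling"].setdefault(tile, []).append(p)
    extra = probes[cfg.n_genes:]
    for k in range(0, len(extra) - 1, 2):
        memberships["cpg_islands"][f"cgi_{k // 2:04d}"] = [extra[k], extra[k + 1]]
    return ProbeAnnotation(positions, memberships)


def promoter_gene_map(ann: ProbeAnnotation) -> Dict[str, str]:
    """promoter region id -> gene name (``prom_<gene>`` -> ``<gene>``)."""
    return {rid: rid[len("prom_"):] for rid in ann.regions("promoters")}


def promoter_probe_of(ann: ProbeAnnotation, gene: str) -> str:
    probes = ann.regions("promoters")[f"prom_{gene}"]
    return probes[0]
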