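"""Truth tables: the exact record of everything the generator planted,
used as the oracle by recovery tests."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from ..variant_consensus import VariantCall, VariantKey

__all__ = ["TruthTables"]


def _v2d(v: VariantCall) -> dict:
    return {"contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "sample_id": v.sample_id}


def _d2v(d: dict) -> VariantCall:
    return VariantCall(d["contig"], d["pos"], d["ref"], d["alt"],
                       d.get("sample_id"))


@dataclass
class TruthTables:
    true_variants: Dict[str, List[VariantCall]] = field(default_factory=dict)
    blacklist_variants: List[VariantCall] = field(default_factory=list)
    germline_variants: Dict[str, List[VariantCall]] = field(default_factory=dict)
    sample_to_individual: Dict[str, str] = field(default_factory=dict)
    shared_artifacts: List[VariantCall] = field(default_factory=list)
    shared_artifact_carriers: Dict[VariantKey, List[str]] = field(default_factory=dict)
    clustered_artifacts: List[List[VariantCall]] = field(default_factory=list)

    planted_degs: Dict[str, float] = field(default_factory=dict)
    planted_dms: Dict[str, float] = field(default_factory=dict)
    coupled_genes: Dict[str, str] = field(default_factory=dict)
    # per-coupled-gene planted per-sample signal: {"samples", "beta", "log2_expr"}
    coupled_signal: Dict[str, Dict[str, list]] = field(default_factory=dict)
    group_labels: Dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        """Check internal disjointness/consistency constraints."""
        true_keys = {v.key for vs in self.true_variants.values() for v in vs}
        artifact_keys = ({v.key for v in self.blacklist_variants}
                         | {v.key for v in self.shared_artifacts}
                         | {v.key for run in self.clustered_artifacts
                            for v in run}
                         | {v.key for vs in self.germline_variants.values()
                            for v in vs})
        if true_keys & artifact_keys:
            raise AssertionError("artifact lists overlap true variants")
        for gene, cls in self.coupled_genes.items():
            if gene not in self.planted_degs:
                raise AssertionError(f"coupled gene {gene} not a planted DEG")
            if cls not in ("hypo-up", "hyper-down"):
                raise AssertionError(f"bad coupled class {cls!r}")

    # -- JSON round trip (text-only artifact) --

    def to_json(self, path) -> None:
        payload = {
            "true_variants": {s: [_v2d(v) for v in vs]
                              for s, vs in self.true_variants.items()},
            "blacklist_variants": [_v2d(v) for v in self.blacklist_variants],
            "germline_variants": {i: [_v2d(v) for v in vs]
                                  for i, vs in self.germline_variants.items()},
            "sample_to_individual": self.sample_to_individual,
            "shared_artifacts": [_v2d(v) for v in self.shared_artifacts],
            "shared_artifact_carriers": {
                "|".join(map(str, k)): v
                for k, v in self.shared_artifact_carriers.items()},
            "clustered_artifacts": [[_v2d(v) for v in run]
                                    for run in self.clustered_artifacts],
            "planted_degs": self.planted_degs,
            "planted_dms": self.planted_dms,
            "coupled_genes": self.coupled_genes,
            "coupled_signal": self.coupled_signal,
            "group_labels": self.group_labels,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthTables":
        with open(path) as fh:
            d = json.load(fh)
        t = cls()
        t.true_variants = {s: [_d2v(x) for x in vs]
                           for s, vs in d["true_variants"].items()}
        t.blacklist_variants = [_d2v(x) for x in d["blacklist_variants"]]
        t.germline_variants = {i: [_d2v(x) for x in vs]
                               for i, vs in d["germline_variants"].items()}
        t.sample_to_individual = d["sample_to_individual"]
        t.shared_artifacts = [_d2v(x) for x in d["shared_artifacts"]]
        for k, v in d["shared_artifact_carriers"].items():
            contig, pos, ref, alt = k.split("|")
            t.shared_artifact_carriers[(contig, int(pos), ref, alt)] = v
        t.clustered_artifacts = [[_d2v(x) for x in run]
                                 for run in d["clustered_artifacts"]]
        t.planted_degs = d["planted_degs"]
        t.planted_dms = d["planted_dms"]
        t.coupled_genes = d["coupled_genes"]
        t.coupled_signal = d.get("coupled_signal", {})
        t.group_labels = d["group_labels"]
        return t
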