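"""Ensemble consensus of multi-caller somatic variant calls plus
post-calling filters (blacklist, germline, shared-across-samples,
clustered-in-window).

Filters flag variants rather than deleting them; the analysis view
(:meth:`ConsensusSet.retained`) excludes flagged records so the full audit
trail is preserved and ``|input| == |retained| + |flagged|`` always holds.
Variant identity is the exact tuple ``(contig, pos, ref, alt)`` after
multi-allelic splitting; coordinates are 1-based (VCF convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

__all__ = [
    "VariantCall",
    "ConsensusVariant",
    "ConsensusSet",
    "classify_alleles",
    "read_vcf",
    "write_vcf",
    "consensus_calls",
    "filter_blacklist",
    "subtract_germline",
    "filter_shared",
    "filter_clustered",
]

_BASES = set("ACGT")

VariantKey = Tuple[str, int, str, str]


def classify_alleles(ref: str, alt: str) -> str:
    """Assign a variant class from REF/ALT allele lengths.

    Returns one of ``SNV``, ``DBS``, ``INS``, ``DEL`` or ``MNV-other``.
    """
    if not ref or not alt or ref == alt:
        raise ValueError(f"invalid allele pair {ref!r}>{alt!r}")
    if any(b not in _BASES for b in ref + alt):
        raise ValueError(f"non-ACGT allele {ref!r}>{alt!r}")
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) == 2 and len(alt) == 2:
        if ref[0] != alt[0] and ref[1] != alt[1]:
            return "DBS"
        return "MNV-other"
    if len(ref) < len(alt) and alt[0] == ref[0]:
        return "INS"
    if len(ref) > len(alt) and ref[0] == alt[0]:
        return "DEL"
    return "MNV-other"


@dataclass(frozen=True, order=True)
class VariantCall:
    """One putative somatic mutation (1-based position)."""

    contig: str
    pos: int
    ref: str
    alt: str
    sample_id: Optional[str] = None
    caller_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        classify_alleles(self.ref, self.alt)  # validates alleles

    @property
    def var_class(self) -> str:
        return classify_alleles(self.ref, self.alt)

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class ConsensusVariant:
    """A consensus variant with caller provenance and filter flags."""

    contig: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    supporting_callers: Set[str] = field(default_factory=set)
    filter_flags: Set[str] = field(default_factory=set)

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def var_class(self) -> str:
        return classify_alleles(self.ref, self.alt)

    @property
    def is_retained(self) -> bool:
        return not self.filter_flags


@dataclass
class ConsensusSet:
    """Per-sample consensus variants plus audit counters."""

    sample_id: str
    variants: List[ConsensusVariant] = field(default_factory=list)
    n_dropped_low_support: int = 0

    def retained(self) -> List[ConsensusVariant]:
        return [v for v in self.variants if v.is_retained]

    def flagged(self) -> List[ConsensusVariant]:
        return [v for v in self.variants if not v.is_retained]

    def __len__(self) -> int:
        return len(self.variants)


# ---------------------------------------------------------------------------
# VCF I/O (plain-text VCF v4.2; one call per ALT allele)
# ---------------------------------------------------------------------------

def read_vcf(path, sample_id: Optional[str] = None,
             caller_id: Optional[str] = None) -> List[VariantCall]:
    """Read a VCF file into a list of :class:`VariantCall`.

    Multi-allelic records are split into one call per ALT allele.
    """
    calls: List[VariantCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}: malformed VCF record at line {lineno}")
            contig, pos_s, _id, ref, alts = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-integer POS at line {lineno}") from exc
            for alt in alts.split(","):
                if alt in (".", "*"):
                    continue
                try:
                    calls.append(VariantCall(contig, pos, ref.upper(),
                                             alt.upper(), sample_id, caller_id))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: bad record at line {lineno}: {exc}") from exc
    return calls


def write_vcf(path, variants: Iterable, contig_lengths: Mapping[str, int]) -> None:
    """Write variants (VariantCall or ConsensusVariant) as minimal VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.contig, v.pos, v.ref, v.alt)):
            flags = getattr(v, "filter_flags", None)
            filt = ";".join(sorted(flags)) if flags else "PASS"
            fh.write(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t.\n")


# ---------------------------------------------------------------------------
# Consensus and filters
# ---------------------------------------------------------------------------

def consensus_calls(callsets: Mapping[str, Sequence[VariantCall]],
                    min_callers: int = 2,
                    sample_id: Optional[str] = None) -> ConsensusSet:
    """Merge per-caller call sets for ONE sample; retain variants supported
    by at least ``min_callers`` callers.

    ``callsets`` maps caller id -> list of calls. Variants seen by fewer
    than ``min_callers`` callers are dropped (counted, not kept).
    """
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    if not callsets:
        raise ValueError("at least one caller required")
    support: Dict[VariantKey, Set[str]] = {}
    order: List[VariantKey] = []
    sid = sample_id
    for caller, calls in callsets.items():
        for call in calls:
            if sid is None:
                sid = call.sample_id
            if call.key not in support:
                support[call.key] = set()
                order.append(call.key)
            support[call.key].add(caller)
    result = ConsensusSet(sample_id=sid or "sample")
    for key in sorted(order):
        callers = support[key]
        if len(callers) >= min_callers:
            contig, pos, ref, alt = key
            result.variants.append(ConsensusVariant(
                contig, pos, ref, alt, result.sample_id,
                supporting_callers=set(callers)))
        else:
            result.n_dropped_low_support += 1
    return result


def filter_blacklist(consensus: ConsensusSet,
                     blacklist: Iterable[VariantCall]) -> ConsensusSet:
    """Flag exact-allele matches against a known-SNP blacklist."""
    keys = {b.key for b in blacklist}
    for v in consensus.variants:
        if v.key in keys:
            v.filter_flags.add("blacklist")
    return consensus


def subtract_germline(consensus: ConsensusSet,
                      germline_calls: Mapping[str, Sequence[VariantCall]],
                      sample_to_individual: Mapping[str, str]) -> ConsensusSet:
    """Flag variants present in the matched individual's germline set.

    ``germline_calls`` maps individual id -> germline variants;
    ``sample_to_individual`` maps analysis sample -> individual.
    """
    sid = consensus.sample_id
    if sid not in sample_to_individual:
        raise KeyError(f"sample {sid!r} has no germline mapping")
    individual = sample_to_individual[sid]
    keys = {g.key for g in germline_calls.get(individual, ())}
    for v in consensus.variants:
        if v.key in keys:
            v.filter_flags.add("germline")
    return consensus


def filter_shared(consensus_by_sample: Mapping[str, ConsensusSet],
                  min_samples: int = 2) -> Mapping[str, ConsensusSet]:
    """Flag variants occurring in >= ``min_samples`` distinct samples.

    Flagging applies in every carrier sample. With a single sample this is
    a warned no-op.
    """
    if len(consensus_by_sample) < 2:
        warnings.warn("filter_shared: fewer than 2 samples; no-op")
        return consensus_by_sample
    carriers: Dict[VariantKey, Set[str]] = {}
    for sid, cs in consensus_by_sample.items():
        for v in cs.variants:
            carriers.setdefault(v.key, set()).add(sid)
    shared = {k for k, s in carriers.items() if len(s) >= min_samples}
    for cs in consensus_by_sample.values():
        for v in cs.variants:
            if v.key in shared:
                v.filter_flags.add("shared")
    return consensus_by_sample


def filter_clustered(consensus: ConsensusSet, window_bp: int = 10,
                     max_in_window: int = 3) -> ConsensusSet:
    """Flag variants lying in any ``window_bp``-base window (inclusive span)
    holding more than ``max_in_window`` variants of this sample.

    Matches the rule "> 3 mutations within a 10 bp window": positions p and
    p + window_bp - 1 are co-windowed.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    by_contig: Dict[str, List[ConsensusVariant]] = {}
    for v in consensus.variants:
        by_contig.setdefault(v.contig, []).append(v)
    for contig_vars in by_contig.values():
        contig_vars.sort(key=lambda v: v.pos)
        n = len(contig_vars)
        i = 0
        for i in range(n):
            j = i
            while j + 1 < n and contig_vars[j + 1].pos - contig_vars[i].pos <= window_bp - 1:
                j += 1
            if j - i + 1 > max_in_window:
                for k in range(i, j + 1):
                    contig_vars[k].filter_flags.add("clustered")
    return consensus


def consensus_table(consensus_by_sample: Mapping[str, ConsensusSet]):
    """Flatten consensus sets to a pandas DataFrame (audit view)."""
    import pandas as pd

    rows = []
    for sid in sorted(consensus_by_sample):
        for v in consensus_by_sample[sid].variants:
            rows.append({
                "contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "sample": sid, "var_class": v.var_class,
                "supporters": ",".join(sorted(v.supporting_callers)),
                "n_supporters": len(v.supporting_callers),
                "flags": ";".join(sorted(v.filter_flags)),
                "retained": v.is_retained,
            })
    return pd.DataFrame(rows, columns=[
        "contig", "pos", "ref", "alt", "sample", "var_class", "supporters",
        "n_supporters", "flags", "retained"])
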