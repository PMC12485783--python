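"""Mutational spectrum classification and comparison.

Classifies SNVs into 96 strand-normalized trinucleotide channels, doublet
substitutions into 78 canonical channels, and small indels into 83
type/length/context/microhomology channels, following the COSMIC v3 catalog
conventions. Also provides per-Mb burden, profile averaging, and cosine
similarity between profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SBS96_LABELS",
    "DBS78_LABELS",
    "ID83_LABELS",
    "SpectrumProfile",
    "BurdenEstimate",
    "revcomp",
    "sbs96_channel",
    "dbs78_channel",
    "id83_channel",
    "build_profile",
    "cosine_similarity",
    "mutational_burden",
    "compare_burdens_welch",
    "average_profiles",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SpectrumError(ValueError):
    """Classification inconsistency (allele/genome mismatch, boundary)."""


# ---------------------------------------------------------------------------
# Canonical channel catalogs
# ---------------------------------------------------------------------------

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

SBS96_LABELS: Tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)

# Canonical doublet catalog: 10 reference doublets with their fixed alt
# sets (one orientation per reverse-complement pair for the palindromic
# references AT/CG/GC/TA), 9+6+9+6+9+6+6+9+9+9 = 78 channels.
_DBS_ALTS = {
    "AC": ("CA", "CG", "CT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "AT": ("CA", "CC", "CG", "GA", "GC", "TA"),
    "CC": ("AA", "AG", "AT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "CG": ("AT", "GC", "GT", "TA", "TC", "TT"),
    "CT": ("AA", "AC", "AG", "GA", "GC", "GG", "TA", "TC", "TG"),
    "GC": ("AA", "AG", "AT", "CA", "CG", "TA"),
    "TA": ("AT", "CG", "CT", "GC", "GG", "GT"),
    "TC": ("AA", "AG", "AT", "CA", "CG", "CT", "GA", "GG", "GT"),
    "TG": ("AA", "AC", "AT", "CA", "CC", "CT", "GA", "GC", "GT"),
    "TT": ("AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG"),
}
_DBS_CANONICAL_REFS = tuple(_DBS_ALTS)

DBS78_LABELS: Tuple[str, ...] = tuple(
    f"{ref}>{alt}" for ref in _DBS_CANONICAL_REFS for alt in _DBS_ALTS[ref]
)


def _id83_labels() -> Tuple[str, ...]:
    labels: List[str] = []
    for base in ("C", "T"):
        labels += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in ("C", "T"):
        labels += [f"1:Ins:{base}:{i}" for i in range(6)]
    for ln in (2, 3, 4, 5):
        labels += [f"{ln}:Del:R:{i}" for i in range(6)]
    for ln in (2, 3, 4, 5):
        labels += [f"{ln}:Ins:R:{i}" for i in range(6)]
    labels += ["2:Del:M:1"]
    labels += [f"3:Del:M:{i}" for i in (1, 2)]
    labels += [f"4:Del:M:{i}" for i in (1, 2, 3)]
    labels += [f"5:Del:M:{i}" for i in (1, 2, 3, 4, 5)]
    return tuple(labels)


ID83_LABELS: Tuple[str, ...] = _id83_labels()

_SCHEMA_LABELS = {"SBS96": SBS96_LABELS, "DBS78": DBS78_LABELS, "ID83": ID83_LABELS}


# ---------------------------------------------------------------------------
# Channel classifiers
# ---------------------------------------------------------------------------

def _contig_seq(genome, contig: str) -> str:
    try:
        return genome.contigs[contig]
    except KeyError as exc:
        raise SpectrumError(f"unknown contig {contig!r}") from exc


def sbs96_channel(v, genome) -> str:
    """Trinucleotide channel of an SNV, pyrimidine-strand normalized."""
    if v.var_class != "SNV":
        raise SpectrumError(f"not an SNV: {v.ref}>{v.alt}")
    seq = _contig_seq(genome, v.contig)
    i = v.pos - 1
    if i < 1 or i + 1 >= len(seq):
        raise SpectrumError(f"{v.contig}:{v.pos} at contig boundary")
    if seq[i] != v.ref:
        raise SpectrumError(
            f"{v.contig}:{v.pos} ref {v.ref} disagrees with genome {seq[i]}")
    five, ref, three, alt = seq[i - 1], v.ref, seq[i + 1], v.alt
    if ref in "AG":  # purine: flip to pyrimidine strand
        five, ref, three, alt = (revcomp(three), revcomp(ref),
                                 revcomp(five), revcomp(alt))
    return f"{five}[{ref}>{alt}]{three}"


def dbs78_channel(v, genome) -> str:
    """Canonical doublet-substitution channel of a DBS."""
    if v.var_class != "DBS":
        raise SpectrumError(f"not a DBS: {v.ref}>{v.alt}")
    seq = _contig_seq(genome, v.contig)
    i = v.pos - 1
    if seq[i:i + 2] != v.ref:
        raise SpectrumError(
            f"{v.contig}:{v.pos} ref {v.ref} disagrees with genome")
    ref, alt = v.ref, v.alt
    # exactly one orientation of (ref, alt) lies in the fixed catalog
    for cand_ref, cand_alt in ((ref, alt), (revcomp(ref), revcomp(alt)),
                               (ref, revcomp(alt))):
        if cand_alt in _DBS_ALTS.get(cand_ref, ()):
            return f"{cand_ref}>{cand_alt}"
    raise SpectrumError(f"unclassifiable doublet {v.ref}>{v.alt}")


def _tandem_copies(unit: str, flank: str) -> int:
    """Perfect tandem copies of ``unit`` at the start of ``flank``."""
    n = 0
    k = len(unit)
    while flank[n * k:(n + 1) * k] == unit:
        n += 1
    return n


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def id83_channel(v, genome) -> str:
    """Indel channel: type, length bin, homopolymer/repeat bin, and, for
    non-repeat deletions of length >= 2, microhomology bin.

    Tandem copies are counted on the 3' side of the (left-anchored) event;
    microhomology is the larger of the deleted-sequence prefix match with
    the 3' flank and suffix match with the 5' flank.
    """
    if v.var_class not in ("INS", "DEL"):
        raise SpectrumError(f"not an indel: {v.ref}>{v.alt}")
    seq = _contig_seq(genome, v.contig)
    i = v.pos - 1  # anchor base index
    if v.var_class == "DEL":
        if seq[i:i + len(v.ref)] != v.ref:
            raise SpectrumError(
                f"{v.contig}:{v.pos} ref {v.ref} disagrees with genome")
        indel = v.ref[1:]
        flank3 = seq[i + len(v.ref):]
        flank5 = seq[:i + 1]
        kind = "Del"
    else:
        if seq[i] != v.ref:
            raise SpectrumError(
                f"{v.contig}:{v.pos} ref {v.ref} disagrees with genome")
        indel = v.alt[1:]
        flank3 = seq[i + 1:]
        flank5 = seq[:i + 1]
        kind = "Ins"
    length = len(indel)
    copies = _tandem_copies(indel, flank3)
    if length == 1:
        base = indel if indel in "CT" else revcomp(indel)
        return f"1:{kind}:{base}:{min(copies, 5)}"
    lenbin = min(length, 5)
    if kind == "Ins":
        return f"{lenbin}:Ins:R:{min(copies, 5)}"
    if copies >= 1:
        return f"{lenbin}:Del:R:{min(copies, 5)}"
    mh = max(_common_prefix(indel, flank3),
             _common_prefix(indel[::-1], flank5[::-1]))
    mh = min(mh, length - 1)
    if mh >= 1:
        return f"{lenbin}:Del:M:{min(mh, 5)}"
    return f"{lenbin}:Del:R:0"


_CLASSIFIERS = {
    "SBS96": (sbs96_channel, ("SNV",)),
    "DBS78": (dbs78_channel, ("DBS",)),
    "ID83": (id83_channel, ("INS", "DEL")),
}


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class SpectrumProfile:
    """Fixed-length channel vector in canonical order."""

    schema: str
    channels: Dict[str, float]
    n_unclassifiable: int = 0

    def __post_init__(self) -> None:
        labels = _SCHEMA_LABELS.get(self.schema)
        if labels is None:
            raise ValueError(f"unknown schema {self.schema!r}")
        full = {lab: float(self.channels.get(lab, 0.0)) for lab in labels}
        if any(c < 0 for c in full.values()):
            raise ValueError("negative channel count")
        extra = set(self.channels) - set(labels)
        if extra:
            raise ValueError(f"labels outside schema: {sorted(extra)[:3]}")
        self.channels = full

    @property
    def labels(self) -> Tuple[str, ...]:
        return _SCHEMA_LABELS[self.schema]

    @property
    def n_total(self) -> float:
        return float(sum(self.channels.values()))

    def as_array(self) -> np.ndarray:
        return np.array([self.channels[lab] for lab in self.labels], dtype=float)

    def normalized(self) -> "SpectrumProfile":
        total = self.n_total
        if total <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        return SpectrumProfile(
            self.schema, {k: c / total for k, c in self.channels.items()},
            self.n_unclassifiable)


@dataclass
class BurdenEstimate:
    n_mutations: int
    callable_bases: int

    def __post_init__(self) -> None:
        if self.callable_bases <= 0:
            raise ValueError("callable_bases must be > 0")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")

    @property
    def burden_per_mb(self) -> float:
        return self.n_mutations * 1e6 / self.callable_bases


def build_profile(variants: Iterable, genome, schema: str) -> SpectrumProfile:
    """Count variants into the schema's channels.

    Variants of the wrong class raise; variants that cannot be classified
    for positional reasons (contig boundary) are tallied separately in
    ``n_unclassifiable`` rather than silently mislabeled.
    """
    classifier, classes = _CLASSIFIERS[schema]
    counts: Dict[str, float] = {}
    n_bad = 0
    for v in variants:
        if v.var_class not in classes:
            raise SpectrumError(
                f"variant class {v.var_class} incompatible with {schema}")
        try:
            lab = classifier(v, genome)
        except SpectrumError as exc:
            if "boundary" in str(exc):
                n_bad += 1
                continue
            raise
        counts[lab] = counts.get(lab, 0.0) + 1.0
    return SpectrumProfile(schema, counts, n_unclassifiable=n_bad)


def cosine_similarity(p: SpectrumProfile, q: SpectrumProfile) -> float:
    if p.schema != q.schema:
        raise ValueError("profiles have different schemas")
    a, b = p.as_array(), q.as_array()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero profile")
    return float(np.dot(a, b) / (na * nb))


def mutational_burden(n_mutations: int, callable_bases: int) -> BurdenEstimate:
    return BurdenEstimate(n_mutations, callable_bases)


def compare_burdens_welch(burdens_a: Sequence[float],
                          burdens_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Welch's t-test on per-sample burden values."""
    from .module_scoring import welch_ttest

    return welch_ttest(burdens_a, burdens_b)


def average_profiles(profiles: Sequence[SpectrumProfile]) -> SpectrumProfile:
    """Arithmetic mean of normalized profiles; the result sums to 1."""
    if not profiles:
        raise ValueError("empty profile list")
    schema = profiles[0].schema
    arrays = [p.normalized().as_array() for p in profiles]
    if any(p.schema != schema for p in profiles):
        raise ValueError("profiles have different schemas")
    mean = np.mean(arrays, axis=0)
    labels = _SCHEMA_LABELS[schema]
    return SpectrumProfile(schema, dict(zip(labels, mean)))


def profile_matrix(profiles: Dict[str, SpectrumProfile], schema: str):
    """Channels x samples DataFrame in canonical row order."""
    import pandas as pd

    labels = list(_SCHEMA_LABELS[schema])
    data = {name: [p.channels[lab] for lab in labels]
            for name, p in profiles.items()}
    return pd.DataFrame(data, index=labels)
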