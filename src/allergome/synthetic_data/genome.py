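"""Synthetic reference sequence."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

__all__ = ["GenomeSequence", "generate_reference", "write_fasta", "read_fasta"]

_BASES = np.array(list("ACGT"))
DEFAULT_CONTIG = "chrS"


@dataclass
class GenomeSequence:
    """Ordered map of contig name -> uppercase base string over ACGT."""

    contigs: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome needs at least one contig")
        for name, seq in self.contigs.items():
            if len(seq) < 1:
                raise ValueError(f"contig {name!r} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name!r} has non-ACGT bases")

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}


def generate_reference(length_bp: int, gc_fraction: float,
                       seed: int) -> GenomeSequence:
    """One random contig of ``length_bp`` bases with the requested GC content.

    Bases are drawn i.i.d. with probabilities (gc/2, gc/2, (1-gc)/2,
    (1-gc)/2) for (C, G, A, T); output is deterministic in ``seed``.
    """
    if length_bp < 1000:
        raise ValueError("length_bp must be >= 1000")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    draws = rng.choice(_BASES, size=length_bp, p=[at, gc, gc, at])
    return GenomeSequence({DEFAULT_CONTIG: "".join(draws)})


def write_fasta(path, genome: GenomeSequence, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> GenomeSequence:
    """Read a FASTA file (whole-contig, small references only)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, rebuild=True)
    contigs = {name: str(fa[name][:]).upper() for name in fa.keys()}
    return GenomeSequence(contigs)
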