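"""Simulated multi-caller somatic variant call sets.

Each sample receives a private set of true somatic variants; every caller
reports each true variant with its configured sensitivity and adds private
false positives at its configured per-Mb rate. On top of that the
generator plants the contaminant classes the consensus filters must
remove: blacklist (known-SNP) variants, per-individual germline variants,
artifacts shared identically across >= 2 samples, and clustered runs of
>= 4 variants within a 10-bp span. All planted positions outside clustered
runs are spaced far enough apart that no accidental cluster can form.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from ..variant_consensus import VariantCall
from .config import SyntheticConfig
from .genome import GenomeSequence, DEFAULT_CONTIG
from .truth import TruthTables

__all__ = ["simulate_callsets"]

_SPACING = 15  # bp between planted anchors; > cluster window, avoids overlap
_MAX_EVENT = 6  # widest ref span a planted variant can occupy


def _draw_variant(rng: np.random.Generator, seq: str, pos: int,
                  var_class: str, contig: str = DEFAULT_CONTIG) -> VariantCall:
    """Create one variant of the requested class anchored at 1-based pos."""
    i = pos - 1
    bases = "ACGT"
    if var_class == "SNV":
        ref = seq[i]
        alt = rng.choice([b for b in bases if b != ref])
        return VariantCall(contig, pos, ref, str(alt))
    if var_class == "DBS":
        ref = seq[i:i + 2]
        alt = "".join(str(rng.choice([b for b in bases if b != r]))
                      for r in ref)
        return VariantCall(contig, pos, ref, alt)
    if var_class == "INS":
        ref = seq[i]
        ins = "".join(rng.choice(list(bases), size=int(rng.integers(1, 4))))
        return VariantCall(contig, pos, ref, ref + ins)
    if var_class == "DEL":
        length = int(rng.integers(1, 4))
        ref = seq[i:i + 1 + length]
        return VariantCall(contig, pos, ref, ref[0])
    raise ValueError(f"unknown variant class {var_class!r}")


def _draw_classes(rng: np.random.Generator, cfg: SyntheticConfig,
                  n: int) -> List[str]:
    classes = sorted(cfg.class_mix)
    probs = [cfg.class_mix[c] for c in classes]
    return [str(c) for c in rng.choice(classes, size=n, p=probs)]


def simulate_callsets(genome: GenomeSequence, cfg: SyntheticConfig,
                      rng: np.random.Generator | None = None
                      ) -> Tuple[Dict[str, Dict[str, List[VariantCall]]],
                                 TruthTables]:
    """Generate per-sample per-caller call sets and exact truth tables.

    Returns ``(callsets, truth)`` with ``callsets[sample][caller]`` a list
    of :class:`VariantCall`.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    contig = next(iter(genome.contigs))
    seq = genome.contigs[contig]
    length = len(seq)

    samples = cfg.samples
    n_samples = len(samples)
    # anchor pool: positions spaced so planted events can never co-cluster
    anchors = np.arange(10, length - _MAX_EVENT - 10, _SPACING)
    rng.shuffle(anchors)
    fp_mean = {c: cfg.caller_fp_rates[c] * length / 1e6 for c in cfg.callers}
    needed = (n_samples * cfg.n_true_variants_per_sample
              + cfg.n_shared_artifacts + cfg.n_blacklist_variants
              + n_samples * cfg.n_germline_variants
              + cfg.n_clustered_artifacts
              + int(4 * n_samples * sum(fp_mean.values())) + 16)
    if needed > len(anchors):
        raise ValueError(
            f"genome too short: need ~{needed} anchor positions, "
            f"have {len(anchors)}")
    pool = iter(int(a) for a in anchors)

    def take(n: int) -> List[int]:
        return [next(pool) for _ in range(n)]

    truth = TruthTables()
    truth.group_labels = dict(cfg.arms)
    callsets: Dict[str, Dict[str, List[VariantCall]]] = {
        s: {c: [] for c in cfg.callers} for s in samples}

    def emit_all_callers(sample: str, v: VariantCall) -> None:
        for c in cfg.callers:
            callsets[sample][c].append(
                VariantCall(v.contig, v.pos, v.ref, v.alt, sample, c))

    # --- true somatic variants, private per sample ---
    for sample in samples:
        n = cfg.n_true_variants_per_sample
        positions = take(n)
        classes = _draw_classes(rng, cfg, n)
        calls = [_draw_variant(rng, seq, p, k, contig)
                 for p, k in zip(positions, classes)]
        truth.true_variants[sample] = [
            VariantCall(v.contig, v.pos, v.ref, v.alt, sample)
            for v in calls]
        for v in truth.true_variants[sample]:
            for c in cfg.callers:
                if rng.random() < cfg.caller_sensitivities[c]:
                    callsets[sample][c].append(
                        VariantCall(v.contig, v.pos, v.ref, v.alt, sample, c))

    # --- caller-private false positives ---
    for sample in samples:
        for c in cfg.callers:
            n_fp = int(rng.poisson(fp_mean[c]))
            for p in take(n_fp):
                v = _draw_variant(rng, seq, p, "SNV", contig)
                callsets[sample][c].append(
                    VariantCall(v.contig, v.pos, v.ref, v.alt, sample, c))

    # --- blacklist (known-SNP) contaminants: one carrier sample each ---
    for p in take(cfg.n_blacklist_variants):
        v = _draw_variant(rng, seq, p, "SNV", contig)
        truth.blacklist_variants.append(v)
        carrier = samples[int(rng.integers(n_samples))]
        emit_all_callers(carrier, v)

    # --- germline variants: one individual per sample ---
    for sample in samples:
        individual = f"mouse_{sample}"
        truth.sample_to_individual[sample] = individual
        glist = []
        for p in take(cfg.n_germline_variants):
            v = _draw_variant(rng, seq, p, "SNV", contig)
            glist.append(v)
            emit_all_callers(sample, v)
        truth.germline_variants[individual] = glist

    # --- artifacts shared identically across >= 2 samples ---
    if cfg.n_shared_artifacts and n_samples >= 2:
        for p in take(cfg.n_shared_artifacts):
            v = _draw_variant(rng, seq, p, "SNV", contig)
            k = int(rng.integers(2, n_samples + 1))
            carriers = rng.choice(samples, size=k, replace=False)
            truth.shared_artifacts.append(v)
            truth.shared_artifact_carriers[v.key] = sorted(str(s) for s in carriers)
            for s in carriers:
                emit_all_callers(str(s), v)

    # --- clustered runs: 4 SNVs within a 10-bp span, one sample each ---
    for p in take(cfg.n_clustered_artifacts):
        run = []
        for off in (0, 3, 6, 9):
            run.append(_draw_variant(rng, seq, p + off, "SNV", contig))
        carrier = samples[int(rng.integers(n_samples))]
        truth.clustered_artifacts.append(run)
        for v in run:
            emit_all_callers(carrier, v)

    for sample in samples:
        for c in cfg.callers:
            callsets[sample][c].sort(key=lambda v: (v.contig, v.pos, v.ref, v.alt))
    return callsets, truth
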