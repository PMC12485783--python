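"""Simulated expression counts, promoter beta values, and inversely
coupled methylation/expression genes.

Noise models are the minimal standard choices for the data types:
negative-binomial counts with per-sample library sizes for RNA-seq and
logit-normal values for beta matrices. Coupled genes share a latent
per-sample factor that enters the two layers with opposite sign, so their
per-sample promoter beta and log2 expression are exactly linearly (hence
monotonically, inversely) related up to ``coupling_noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ..methylation_analysis import ProbeAnnotation
from .annotation import (build_probe_annotation, gene_names, probe_names,
                         promoter_gene_map)
from .callsets import simulate_callsets
from .config import SyntheticConfig, stream_rngs
from .genome import GenomeSequence, generate_reference
from .truth import TruthTables

__all__ = [
    "simulate_expression",
    "simulate_methylation",
    "simulate_coupled_genes",
    "simulate_benchmark",
    "BenchmarkData",
]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = mu + disp*mu^2)."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_expression(cfg: SyntheticConfig,
                        rng: Optional[np.random.Generator] = None,
                        deg_up: Optional[Sequence[str]] = None,
                        deg_down: Optional[Sequence[str]] = None
                        ) -> Tuple[pd.DataFrame, pd.Series, TruthTables]:
    """Negative-binomial count matrix with planted up/down DEGs.

    Returns ``(counts, gene_lengths, truth)``. DEG gene identities may be
    supplied explicitly (benchmark role allocation) or are drawn here.
    """
    if cfg.n_genes < cfg.n_deg_up + cfg.n_deg_down:
        raise ValueError("n_genes < planted DEG count")
    if rng is None:
        rng = stream_rngs(cfg.seed)["counts"]
    genes = gene_names(cfg.n_genes)
    samples = list(cfg.samples)
    if deg_up is None or deg_down is None:
        picks = rng.choice(genes, size=cfg.n_deg_up + cfg.n_deg_down,
                           replace=False)
        deg_up = [str(g) for g in picks[:cfg.n_deg_up]]
        deg_down = [str(g) for g in picks[cfg.n_deg_up:]]

    base = rng.lognormal(mean=np.log(150.0), sigma=1.0, size=cfg.n_genes)
    lengths = pd.Series(
        rng.integers(500, 5000, size=cfg.n_genes).astype(float),
        index=genes, name="length")
    lo, hi = cfg.lib_size_range
    libsize = rng.integers(lo, hi + 1, size=len(samples)).astype(float)
    depth = libsize / libsize.mean()

    lfc = pd.Series(0.0, index=genes)
    lfc.loc[list(deg_up)] = cfg.deg_log2fc
    lfc.loc[list(deg_down)] = -cfg.deg_log2fc
    is_hdm = np.array([s.startswith("HDM") for s in samples])
    fold = np.where(is_hdm[None, :], 2.0 ** lfc.values[:, None], 1.0)
    mean = base[:, None] * depth[None, :] * fold
    counts = _nb_draw(rng, mean, cfg.nb_dispersion)

    truth = TruthTables()
    truth.group_labels = dict(cfg.arms)
    if cfg.deg_log2fc != 0:  # zero effect size plants nothing
        truth.planted_degs = {g: float(cfg.deg_log2fc) for g in deg_up}
        truth.planted_degs.update({g: float(-cfg.deg_log2fc) for g in deg_down})
    return (pd.DataFrame(counts, index=genes, columns=samples),
            lengths, truth)


def simulate_methylation(cfg: SyntheticConfig, promoter_map: ProbeAnnotation,
                         rng: Optional[np.random.Generator] = None,
                         hyper_probes: Optional[Sequence[str]] = None,
                         hypo_probes: Optional[Sequence[str]] = None
                         ) -> Tuple[pd.DataFrame, TruthTables]:
    """Logit-normal beta matrix with planted hyper/hypo DMSs.

    Planted probes shift the treated-arm group mean by exactly
    +/- ``delta_beta_planted`` in the noiseless limit.
    """
    if cfg.n_probes < cfg.n_hyper + cfg.n_hypo:
        raise ValueError("n_probes < planted DMS count")
    delta = cfg.delta_beta_planted
    if 0.95 - delta < 0.20:
        raise ValueError(
            f"delta_beta_planted={delta} saturates the feasible beta range")
    if rng is None:
        rng = stream_rngs(cfg.seed)["betas"]
    probes = list(promoter_map.probe_positions.index)
    samples = list(cfg.samples)
    if hyper_probes is None or hypo_probes is None:
        picks = rng.choice(probes, size=cfg.n_hyper + cfg.n_hypo, replace=False)
        hyper_probes = [str(p) for p in picks[:cfg.n_hyper]]
        hypo_probes = [str(p) for p in picks[cfg.n_hyper:]]

    base = pd.Series(rng.uniform(0.30, 0.70, size=len(probes)), index=probes)
    # keep planted probes inside the feasible window for the shift
    base.loc[list(hyper_probes)] = rng.uniform(0.20, 0.95 - delta,
                                               size=len(hyper_probes))
    base.loc[list(hypo_probes)] = rng.uniform(0.05 + delta, 0.80,
                                              size=len(hypo_probes))

    shift = pd.Series(0.0, index=probes)
    shift.loc[list(hyper_probes)] = delta
    shift.loc[list(hypo_probes)] = -delta
    is_hdm = np.array([s.startswith("HDM") for s in samples])
    mean_beta = np.where(is_hdm[None, :],
                         (base + shift).values[:, None],
                         base.values[:, None])
    logits = logit(mean_beta) + rng.normal(
        0.0, cfg.logit_noise_sd, size=mean_beta.shape)
    beta = expit(logits)

    truth = TruthTables()
    truth.group_labels = dict(cfg.arms)
    truth.planted_dms = {p: float(delta) for p in hyper_probes}
    truth.planted_dms.update({p: float(-delta) for p in hypo_probes})
    return pd.DataFrame(beta, index=probes, columns=samples), truth


def simulate_coupled_genes(counts: pd.DataFrame, beta: pd.DataFrame,
                           truth: TruthTables, cfg: SyntheticConfig,
                           ann: ProbeAnnotation,
                           rng: Optional[np.random.Generator] = None,
                           coupled_hypo_up: Optional[Sequence[str]] = None,
                           coupled_hyper_down: Optional[Sequence[str]] = None
                           ) -> Tuple[pd.DataFrame, pd.DataFrame, TruthTables]:
    """Overwrite the rows of the coupled genes in both layers with an
    inversely coupled signal and record them in the truth tables.

    Per coupled gene the promoter beta is ``arm_base + amp * u_s`` (with a
    deterministic latent spread ``u`` across the samples of each arm) and
    the log2 expression is an exactly decreasing linear function of that
    beta plus ``Normal(0, coupling_noise_sd)`` noise — so the planted
    per-sample Pearson correlation tends to -1 as the noise vanishes.
    """
    if cfg.coupling_noise_sd < 0:
        raise ValueError("coupling_noise_sd must be >= 0")
    if rng is None:
        rng = stream_rngs(cfg.seed)["coupling"]
    gene_map = promoter_gene_map(ann)
    probe_of = {g: ann.regions("promoters")[rid][0]
                for rid, g in gene_map.items()}
    if coupled_hypo_up is None or coupled_hyper_down is None:
        taken = set(truth.planted_degs) | {
            g for g in probe_of if probe_of[g] in truth.planted_dms}
        free = [g for g in counts.index if g in probe_of and g not in taken]
        n = cfg.n_coupled
        if len(free) < n:
            raise ValueError("not enough eligible genes for coupling")
        picks = rng.choice(free, size=n, replace=False)
        coupled_hypo_up = [str(g) for g in picks[:cfg.n_coupled_hypo_up]]
        coupled_hyper_down = [str(g) for g in picks[cfg.n_coupled_hypo_up:]]

    samples = list(counts.columns)
    arms = np.array([s.split("_")[0] for s in samples])
    depth = counts.sum(axis=0).values / counts.sum(axis=0).mean()
    n_per_arm = {a: int((arms == a).sum()) for a in np.unique(arms)}
    u = np.empty(len(samples))
    for a, n in n_per_arm.items():
        u[arms == a] = np.linspace(-1.0, 1.0, n) if n > 1 else 0.0

    delta = cfg.coupled_delta_beta
    lfc = cfg.coupling_slope * delta
    counts = counts.copy()
    beta = beta.copy()
    arm_idx = {a: np.flatnonzero(arms == a) for a in np.unique(arms)}
    for gene, klass in ([(g, "hypo-up") for g in coupled_hypo_up]
                        + [(g, "hyper-down") for g in coupled_hyper_down]):
        probe = probe_of[gene]
        if klass == "hypo-up":
            arm_base = np.where(arms == "HDM", 0.65 - delta, 0.65)
        else:
            arm_base = np.where(arms == "HDM", 0.30 + delta, 0.30)
        # independent within-arm assignment of the latent spread per gene,
        # so coupled genes do not shift library composition in lockstep
        ug = u.copy()
        for idx in arm_idx.values():
            ug[idx] = rng.permutation(ug[idx])
        b = arm_base + cfg.coupled_beta_amp * ug + rng.normal(0, 0.005,
                                                              len(samples))
        b = np.clip(b, 0.01, 0.99)
        y = (cfg.coupled_base_log2_expr
             + cfg.coupling_slope * (0.5 - b)
             + rng.normal(0.0, cfg.coupling_noise_sd, len(samples)))
        beta.loc[probe] = b
        counts.loc[gene] = np.rint(np.exp2(y) * depth).astype(int)
        sign = 1.0 if klass == "hypo-up" else -1.0
        truth.coupled_genes[gene] = klass
        truth.planted_degs[gene] = sign * lfc
        truth.planted_dms[probe] = -sign * delta
        truth.coupled_signal[gene] = {
            "samples": samples,
            "beta": [float(x) for x in b],
            "log2_expr": [float(x) for x in y],
        }
    return counts, beta, truth


@dataclass
class BenchmarkData:
    """Everything one synthetic end-to-end run produces."""

    cfg: SyntheticConfig
    genome: GenomeSequence
    callsets: Dict[str, Dict[str, list]]
    counts: pd.DataFrame
    gene_lengths: pd.Series
    beta: pd.DataFrame
    annotation: ProbeAnnotation
    truth: TruthTables


def simulate_benchmark(cfg: SyntheticConfig,
                       with_variants: bool = True) -> BenchmarkData:
    """Generate the full coordinated benchmark under one root seed.

    Gene roles (coupled, DEG-only, promoter-DMS-only, null) are allocated
    disjointly, so the DEG/DMG intersection outside the coupled genes is
    empty by construction.
    """
    rngs = stream_rngs(cfg.seed)
    genes = gene_names(cfg.n_genes)
    ann = build_probe_annotation(cfg)
    probe_of = {g: f"p{i:04d}" for i, g in enumerate(genes)}

    shuffled = list(genes)
    rngs["coupling"].shuffle(shuffled)
    need = (cfg.n_coupled + cfg.n_deg_up + cfg.n_deg_down
            + cfg.n_hyper + cfg.n_hypo)
    if need > cfg.n_genes:
        raise ValueError("n_genes too small for the requested planted roles")
    it = iter(shuffled)

    def take(n: int) -> List[str]:
        return [next(it) for _ in range(n)]

    coupled_up = take(cfg.n_coupled_hypo_up)
    coupled_down = take(cfg.n_coupled_hyper_down)
    deg_up = take(cfg.n_deg_up)
    deg_down = take(cfg.n_deg_down)
    hyper_probes = [probe_of[g] for g in take(cfg.n_hyper)]
    hypo_probes = [probe_of[g] for g in take(cfg.n_hypo)]

    counts, lengths, expr_truth = simulate_expression(
        cfg, rng=rngs["counts"], deg_up=deg_up, deg_down=deg_down)
    beta, meth_truth = simulate_methylation(
        cfg, ann, rng=rngs["betas"],
        hyper_probes=hyper_probes, hypo_probes=hypo_probes)

    truth = expr_truth
    truth.planted_dms = meth_truth.planted_dms
    counts, beta, truth = simulate_coupled_genes(
        counts, beta, truth, cfg, ann, rng=rngs["coupling"],
        coupled_hypo_up=coupled_up, coupled_hyper_down=coupled_down)

    genome = generate_reference(
        cfg.genome_length_bp, cfg.gc_fraction,
        seed=int(rngs["genome"].integers(2 ** 31)))
    callsets: Dict[str, Dict[str, list]] = {}
    if with_variants:
        callsets, var_truth = simulate_callsets(genome, cfg,
                                                rng=rngs["variants"])
        truth.true_variants = var_truth.true_variants
        truth.blacklist_variants = var_truth.blacklist_variants
        truth.germline_variants = var_truth.germline_variants
        truth.sample_to_individual = var_truth.sample_to_individual
        truth.shared_artifacts = var_truth.shared_artifacts
        truth.shared_artifact_carriers = var_truth.shared_artifact_carriers
        truth.clustered_artifacts = var_truth.clustered_artifacts
    truth.validate()
    return BenchmarkData(cfg, genome, callsets, counts, lengths, beta,
                         ann, truth)
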