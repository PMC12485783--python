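"""Benchmark configuration and seed-stream management.

A single root seed deterministically derives one independent random stream
per generation stage (genome, variants, counts, betas, coupling) so any
stage can be re-run in isolation and reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import numpy as np
import yaml

__all__ = ["SyntheticConfig", "load_config", "stream_rngs", "STREAMS"]

STREAMS = ("genome", "variants", "counts", "betas", "coupling")

DEFAULT_CALLERS = ("callerA", "callerB", "callerC", "callerD")


@dataclass
class SyntheticConfig:
    seed: int = 42

    # reference
    genome_length_bp: int = 100_000
    gc_fraction: float = 0.45

    # variant layer
    n_samples_per_arm: int = 3
    n_true_variants_per_sample: int = 300
    caller_sensitivities: Dict[str, float] = field(
        default_factory=lambda: {c: 0.9 for c in DEFAULT_CALLERS})
    caller_fp_rates: Dict[str, float] = field(
        default_factory=lambda: {c: 50.0 for c in DEFAULT_CALLERS})
    n_shared_artifacts: int = 8
    n_clustered_artifacts: int = 3
    n_blacklist_variants: int = 10
    n_germline_variants: int = 15
    class_mix: Dict[str, float] = field(
        default_factory=lambda: {"SNV": 0.70, "DBS": 0.10, "INS": 0.10,
                                 "DEL": 0.10})

    # expression layer
    n_genes: int = 2000
    n_deg_up: int = 100
    n_deg_down: int = 100
    deg_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    lib_size_range: Tuple[int, int] = (800_000, 1_200_000)

    # methylation layer
    n_probes: int = 3000
    n_hyper: int = 80
    n_hypo: int = 80
    delta_beta_planted: float = 0.30
    logit_noise_sd: float = 0.15

    # coupled genes (inverse promoter-methylation / expression relation)
    n_coupled_hypo_up: int = 12
    n_coupled_hyper_down: int = 8
    coupling_noise_sd: float = 0.02
    coupled_delta_beta: float = 0.35
    coupled_beta_amp: float = 0.03
    coupling_slope: float = 15.0
    coupled_base_log2_expr: float = 7.5

    def __post_init__(self) -> None:
        counts = [
            self.genome_length_bp, self.n_samples_per_arm,
            self.n_true_variants_per_sample, self.n_shared_artifacts,
            self.n_clustered_artifacts, self.n_blacklist_variants,
            self.n_germline_variants, self.n_genes, self.n_deg_up,
            self.n_deg_down, self.n_probes, self.n_hyper, self.n_hypo,
            self.n_coupled_hypo_up, self.n_coupled_hyper_down,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must lie in (0, 1)")
        for name, probs in (("caller_sensitivities", self.caller_sensitivities),):
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(r < 0 for r in self.caller_fp_rates.values()):
            raise ValueError("caller_fp_rates must be >= 0")
        if set(self.caller_sensitivities) != set(self.caller_fp_rates):
            raise ValueError("caller name sets disagree")
        if not 0 < self.delta_beta_planted < 1:
            raise ValueError("delta_beta_planted must lie in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.coupling_noise_sd < 0:
            raise ValueError("coupling_noise_sd must be >= 0")
        if self.logit_noise_sd < 0:
            raise ValueError("logit_noise_sd must be >= 0")
        if self.n_genes < self.n_deg_up + self.n_deg_down + self.n_coupled:
            raise ValueError("n_genes too small for planted DEGs")
        if self.lib_size_range[0] > self.lib_size_range[1]:
            raise ValueError("lib_size_range must be (lo, hi)")
        mix = sum(self.class_mix.values())
        if abs(mix - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")

    @property
    def callers(self) -> Tuple[str, ...]:
        return tuple(sorted(self.caller_sensitivities))

    @property
    def n_coupled(self) -> int:
        return self.n_coupled_hypo_up + self.n_coupled_hyper_down

    @property
    def samples(self) -> Tuple[str, ...]:
        n = self.n_samples_per_arm
        return tuple([f"HDM_{i+1}" for i in range(n)]
                     + [f"VEH_{i+1}" for i in range(n)])

    @property
    def arms(self) -> Dict[str, str]:
        return {s: s.split("_")[0] for s in self.samples}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lib_size_range"] = list(self.lib_size_range)
        return d


def load_config(path) -> SyntheticConfig:
    """Load a SyntheticConfig from a YAML file (missing keys -> defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "lib_size_range" in data:
        data["lib_size_range"] = tuple(data["lib_size_range"])
    return SyntheticConfig(**data)


def stream_rngs(seed: int) -> Dict[str, np.random.Generator]:
    """Named, independent random streams derived from one root seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(STREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(STREAMS, children)}
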