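import numpy as np
import pytest

from allergome.synthetic_data import (SyntheticConfig, generate_reference,
                                      simulate_benchmark)


@pytest.fixture(scope="session")
def small_genome():
    return generate_reference(20_000, 0.45, seed=7)


@pytest.fixture(scope="session")
def fast_config():
    """Scaled-down benchmark config for quick end-to-end tests."""
    return SyntheticConfig(
        seed=11,
        genome_length_bp=30_000,
        n_true_variants_per_sample=60,
        caller_fp_rates={c: 30.0 for c in
                         ("callerA", "callerB", "callerC", "callerD")},
        n_shared_artifacts=4,
        n_clustered_artifacts=2,
        n_blacklist_variants=5,
        n_germline_variants=5,
        n_genes=800,
        n_deg_up=30,
        n_deg_down=30,
        n_probes=1200,
        n_hyper=25,
        n_hypo=25,
    )


@pytest.fixture(scope="session")
def fast_benchmark(fast_config):
    return simulate_benchmark(fast_config)


@pytest.fixture(scope="session")
def default_benchmark():
    """The full default benchmark (seed 42) used by the acceptance targets."""
    return simulate_benchmark(SyntheticConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
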