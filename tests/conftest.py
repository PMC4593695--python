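import pytest

from concordia import SimulationConfig, simulate_expression, simulate_genome


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured study: decoys, ID-fallback probes, changes."""
    return SimulationConfig(
        seed=1,
        n_chromosomes=2,
        n_transcripts=60,
        n_array_probes=80,
        decoy_fraction=0.1,
        id_fallback_fraction=0.05,
        n_genes_changed=10,
        library_sizes=(50_000, 50_000),
        n_qpcr_genes=10,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_expression(small_config)


@pytest.fixture(scope="session")
def clean_config(small_config):
    """Noise-free variant: every stochastic term off, unit gains."""
    return small_config.with_(
        array_noise_sd=0.0,
        dye_bias_cy3=1.0,
        dye_bias_cy5=1.0,
        crosstalk_alpha=0.0,
        nb_dispersion=0.0,
        qpcr_ct_noise_sd=0.0,
    )
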