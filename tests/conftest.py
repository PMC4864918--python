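import pytest

from asmbench.simulate import QualityModel, simulate_genome


@pytest.fixture(scope="session")
def genome_low_gc():
    """200 kb repeat-free genome at 35.4 % GC."""
    return simulate_genome(200_000, 0.354, seed=5)


@pytest.fixture(scope="session")
def genome_mid_gc():
    return simulate_genome(200_000, 0.522, seed=5)


@pytest.fixture(scope="session")
def genome_high_gc():
    return simulate_genome(200_000, 0.730, seed=5)


@pytest.fixture(scope="session")
def genome_two_replicons():
    """Two-replicon genome for translocation fixtures."""
    return simulate_genome(60_000, 0.50, seed=2, n_replicons=2)


@pytest.fixture(scope="session")
def flat_quality():
    """Noise-free quality model: every base Phred 30."""
    return QualityModel(
        q_start=30.0, decay_per_cycle=0.0, gc_penalty=0.0,
        insert_penalty=0.0, noise_sd=0.0, read_noise_sd=0.0,
    )
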