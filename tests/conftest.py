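import pytest

from viromet.synthdata import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale scenario used by unit tests (fast to generate)."""
    return SynthConfig(
        seed=7,
        n_pathways=30,
        kos_per_pathway=(5, 20),
        ko_pool_size=300,
        compound_pool_size=120,
        n_background_reads=20_000,
        n_subset_reads=500,
        n_planted=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)
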