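import pytest

from digitag.simulate import SimConfig, simulate_library


@pytest.fixture(scope="session")
def small_library():
    """A small error-free library with well-separated tags: 20 positions,
    10 molecules each, 3 PCR copies per molecule."""
    config = SimConfig(
        n_positions=20,
        molecules_per_position=10,
        pcr_copies=("fixed", 3),
        umi_error_rate=0.0,
        min_tag_distance=2,
        read_length=30,
        seed=42,
    )
    records, truth = simulate_library(config)
    return config, records, truth
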