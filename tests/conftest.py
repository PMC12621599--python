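import pytest

from tailscape.simulate import SimConfig, generate_reads, generate_reference


@pytest.fixture(scope="session")
def small_sim():
    """A 60-gene mixed simulation shared by read-level tests."""
    config = SimConfig(seed=7, n_genes=60)
    reference = generate_reference(config)
    reads, truth = generate_reads(config, reference)
    return config, reference, reads, truth


@pytest.fixture(scope="session")
def default_sim():
    """The default 500-gene mixed simulation (criterion-scale conditions)."""
    config = SimConfig(seed=1)
    reference = generate_reference(config)
    reads, truth = generate_reads(config, reference)
    return config, reference, reads, truth
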