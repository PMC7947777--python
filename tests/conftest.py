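import pytest

from macrosyn.simulate import SimulationConfig, simulate_pair


@pytest.fixture(scope="session")
def small_pair():
    """A small simulated genome pair shared by read-only tests."""
    cfg = SimulationConfig(seed=11, n_chrom=4, genes_per_chrom=150)
    genome_a, genome_b, orthologs, truth = simulate_pair(cfg)
    return cfg, genome_a, genome_b, orthologs, truth
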