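import numpy as np
import pytest

from rdrmap.genome import Gene, GenomeAnnotation, Replicon
from rdrmap.simulate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def toy_genome() -> GenomeAnnotation:
    """A hand-built two-replicon genome with known gene layout."""
    rng = np.random.default_rng(7)
    seq1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
    seq2 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3_000)])
    genes = [
        Gene("gA", "chr1", 1000, 2000, "+"),
        Gene("gB", "chr1", 2100, 3000, "+"),      # tandem, gap 100
        Gene("gC", "chr1", 3500, 4400, "-"),
        Gene("gD", "chr1", 4600, 5500, "+"),      # divergent with gC
        Gene("gE", "chr1", 5550, 6400, "+"),      # tandem, gap 50
        Gene("tR", "chr1", 7000, 7080, "tRNA".replace("tRNA", "+"), kind="tRNA"),
        Gene("gF", "chr2", 200, 1400, "-"),
    ]
    return GenomeAnnotation([Replicon("chr1", seq1), Replicon("chr2", seq2)], genes)


@pytest.fixture(scope="session")
def small_sim():
    """A compact synthetic study shared across tests (fixed seed)."""
    config = SimulationConfig(
        seed=11,
        n_genes=60,
        replicon_lengths=(45_000, 20_000, 10_000),
        regulon_size=6,
    )
    genome, truth = simulate_genome(config)
    return config, genome, truth
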