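import numpy as np
import pytest

from paleovar.genome_sim import GenomeSimConfig, simulate_pair


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def low_pair():
    """A small low-divergence reference/diploid pair shared across tests."""
    return simulate_pair(
        GenomeSimConfig(length_bp=80_000, gc_content=0.5, divergence_level="low", seed=11)
    )


@pytest.fixture(scope="session")
def high_pair():
    return simulate_pair(
        GenomeSimConfig(length_bp=80_000, gc_content=0.5, divergence_level="high", seed=12)
    )


@pytest.fixture(scope="session")
def flat_chromosome(rng):
    """A 40 kb random 50% GC sequence used as a stand-alone chromosome."""
    return "".join(np.random.default_rng(5).choice(list("ACGT"), size=40_000))
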