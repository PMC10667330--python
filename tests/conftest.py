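import numpy as np
import pytest

from chromoforge import apply_design
from chromoforge.fixtures import ToyChromosomeSpec, make_toy_chromosome

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def toy():
    """A standard 60-kb toy chromosome with its truth table."""
    spec = ToyChromosomeSpec(seed=12)
    genome, truth = make_toy_chromosome(spec)
    return genome, truth


@pytest.fixture(scope="session")
def designed_toy(toy):
    """The standard toy run through the design engine with default policy."""
    genome, truth = toy
    designed, ledger, summary = apply_design(genome)
    return genome, truth, designed, ledger, summary
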