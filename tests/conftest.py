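import numpy as np
import pytest

from svindel.alignio import extract_murs
from svindel.candidates import detect_candidates
from svindel.simdata import SimConfig, simulate

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture(scope="session")
def small_sim():
    """A compact error-free simulation: 30 kb, 6 deletions, 4 insertions."""
    config = SimConfig(
        genome_length=30_000,
        n_deletions=6,
        deletion_length=(30, 300),
        n_insertions=4,
    )
    return simulate(config, seed=11)


@pytest.fixture(scope="session")
def small_sim_candidates(small_sim):
    murs = extract_murs(small_sim.records)
    return detect_candidates(murs, small_sim.reference)


@pytest.fixture(scope="session")
def dup_sim():
    """Simulation with a duplicated segment: yields N-UMRs and false
    (shifted-copy) candidates alongside the true ones."""
    config = SimConfig(
        genome_length=40_000,
        n_deletions=8,
        deletion_length=(30, 300),
        n_insertions=4,
        dup_length=2000,
    )
    return simulate(config, seed=5)
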