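import numpy as np
import pytest

from hemitect.classify_trim import TEConsensus
from hemitect.simulate import SimConfig, random_genome, synthetic_consensus

BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def mutate(seq, positions):
    """Substitute each given 0-based position to a different base."""
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = flip[out[p]]
    return "".join(out)


@pytest.fixture(scope="session")
def consensus_seq():
    return synthetic_consensus()


@pytest.fixture(scope="session")
def consensus(consensus_seq):
    return TEConsensus(consensus_seq)


@pytest.fixture(scope="session")
def toy_genome():
    return random_genome({"chrA": 60_000, "chrB": 40_000}, seed=101)


@pytest.fixture()
def errorfree_cfg():
    return SimConfig(seed=42, sub_rate_polymerase=0.0, sub_rate_sequencer=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
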