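import numpy as np
import pytest

from bandpop.io_core import BandMatrix, PopulationMap


@pytest.fixture
def tiny_matrix() -> BandMatrix:
    """4 accessions x 5 loci over 2 primers, no missing calls."""
    calls = np.array(
        [
            [1, 0, 1, 1, 0],
            [0, 1, 1, 1, 0],
            [1, 1, 0, 1, 0],
            [0, 0, 1, 1, 0],
        ],
        dtype=np.int8,
    )
    return BandMatrix(
        ["a1", "a2", "a3", "a4"],
        ["P1.1", "P1.2", "P1.3", "P2.1", "P2.2"],
        calls,
        {"P1.1": "P1", "P1.2": "P1", "P1.3": "P1", "P2.1": "P2", "P2.2": "P2"},
    )


@pytest.fixture
def tiny_pops() -> PopulationMap:
    return PopulationMap({"a1": "g1", "a2": "g1", "a3": "g2", "a4": "g2"})


@pytest.fixture
def two_block_matrix() -> BandMatrix:
    """Two groups of near-identical accessions fixed for disjoint band sets."""
    rng = np.random.default_rng(11)
    block = np.zeros((8, 40), dtype=np.int8)
    block[:4, :20] = 1
    block[4:, 20:] = 1
    # sprinkle a little within-block variation so distances are not all 0
    for i in range(8):
        j = rng.integers(0, 40, size=2)
        block[i, j] = 1 - block[i, j]
    ids = [f"x{i}" for i in range(4)] + [f"y{i}" for i in range(4)]
    loci = [f"P1.{j + 1}" for j in range(40)]
    return BandMatrix(ids, loci, block, {l: "P1" for l in loci})
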