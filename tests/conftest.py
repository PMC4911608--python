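import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper

from apoclass import (
    AminoAcidMatrix,
    GenePartition,
    RootedTree,
    ScreeningConfig,
    SimulationParams,
    simulate,
)


@pytest.fixture
def quartet_tree():
    return RootedTree.from_newick("((A,B),(C,D));", outgroup=["D"])


@pytest.fixture
def quartet_matrix():
    def make(col_strings):
        # col_strings: list of 4-character strings, one per column (A,B,C,D)
        rows = ["".join(cs[i] for cs in col_strings) for i in range(4)]
        return AminoAcidMatrix(["A", "B", "C", "D"], rows)

    return make


@pytest.fixture
def clean_sim():
    """Clean balanced simulation: the acceptance-scale study conditions."""
    return simulate(SimulationParams(seed=42))


@pytest.fixture
def screening_config():
    return ScreeningConfig()
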