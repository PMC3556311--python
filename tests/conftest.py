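import numpy as np
import pytest

from trnhier import (LevelAssignment, build_pair_set, example_network)

#: the decomposition reported for the worked example (1-based levels)
PRINTED_LEVELS = {"n1": 4, "n2": 3, "n3": 3, "n4": 2, "n5": 2, "n6": 2,
                  "n7": 1}


@pytest.fixture
def example_net():
    return example_network()


@pytest.fixture
def example_adj(example_net):
    return build_pair_set(example_net, "adjacency")


@pytest.fixture
def example_reach(example_net):
    return build_pair_set(example_net, "reachability")


@pytest.fixture
def printed_assignment():
    return LevelAssignment.from_one_based(PRINTED_LEVELS, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
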