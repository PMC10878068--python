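import numpy as np
import pytest

from hyperfilter import Hypergraph


@pytest.fixture
def toy():
    """Edges of sizes 2, 3 and 4 with one shared pair."""
    return Hypergraph(edges=[{1, 2}, {1, 2, 3}, {2, 3, 4, 5}])


@pytest.fixture
def path3():
    """Path hypergraph 1 - 2 - 3 (two dyads sharing node 2)."""
    return Hypergraph(edges=[{1, 2}, {2, 3}])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
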