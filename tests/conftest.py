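import networkx as nx
import numpy as np
import pytest

from fluencynet import FluencyCorpus, FluencyList, WalkSimulator


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_bac():
    """Path graph b - a - c (the worked transition example)."""
    return nx.Graph([("b", "a"), ("a", "c")])


@pytest.fixture
def single_edge():
    return nx.Graph([("a", "b")])


def make_corpus(lists, pid="p1"):
    return FluencyCorpus(
        pid, tuple(FluencyList(pid, f"l{i}", tuple(items)) for i, items in enumerate(lists))
    )


@pytest.fixture
def toy_corpus():
    return make_corpus([["a", "b", "c"], ["c", "b", "a"]])


def simulate_corpus(net, p_emit, n_lists, n_emissions, seed, pid="sim"):
    """Corpus of noisy-censored-walk lists from a known network."""
    rng = np.random.default_rng(seed)
    sim = WalkSimulator(net)
    lists = [
        FluencyList(pid, f"l{i}", tuple(sim.sample_emissions(p_emit, n_emissions, rng)))
        for i in range(n_lists)
    ]
    return FluencyCorpus(pid, tuple(lists))


@pytest.fixture
def ws10():
    """Connected 10-node Watts-Strogatz graph used in recovery tests."""
    g = nx.connected_watts_strogatz_graph(10, 4, 0.2, seed=1)
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g})
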