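"""Likelihood of fluency lists under the noisy censored random walk.

The closed-form worked example (path b-a-c) is derived by the renewal
series: from a, the walk emits c directly (prob 1/2 per attempt), emits b
(reach b then emit: 1/2 * 1/2), emits a (reach b censored, return, emit:
1/8), or returns to a censored (1/8) and renews.  Summing the geometric
series gives P(c) = 4/7, P(b) = 2/7, P(a) = 1/7 — and the same numbers fall
out of the fundamental-matrix computation and a Monte-Carlo simulation.
"""

import math

import networkx as nx
import numpy as np
import pytest

from conftest import make_corpus, simulate_corpus
from fluencynet import (
    FluencyList,
    PEMIT_GRID,
    build_transition_matrix,
    corpus_log_likelihood,
    corpus_log_likelihood_grid,
    emission_distribution,
    initial_item_prob,
    list_log_likelihood,
    transition_prob,
)


def random_graph(n, seed, p=0.5):
    g = nx.erdos_renyi_graph(n, p, seed=seed)
    while not nx.is_connected(g):
        seed += 100
        g = nx.erdos_renyi_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"v{i}" for i in g})


class TestTransitionMatrix:
    def test_path_row(self):
        tm = build_transition_matrix(nx.path_graph(["a", "b", "c"]))
        b = tm.index["b"]
        assert tm.matrix[b, tm.index["a"]] == 0.5
        assert tm.matrix[b, tm.index["c"]] == 0.5

    def test_complete_graph_rows(self):
        tm = build_transition_matrix(nx.complete_graph(4))
        off = tm.matrix[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1 / 3)

    @pytest.mark.parametrize("seed", range(3))
    def test_rows_sum_to_one(self, seed):
        tm = build_transition_matrix(random_graph(8, seed))
        assert np.allclose(tm.matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_isolated_node_flagged(self):
        g = nx.Graph([("a", "b")])
        g.add_node("z")
        tm = build_transition_matrix(g)
        assert tm.isolated == {"z"}
        assert np.all(tm.matrix[tm.index["z"]] == 0.0)


class TestInitialItemProb:
    @pytest.mark.parametrize(
        "graph,item,expected",
        [
            (nx.star_graph(["x", "l1", "l2", "l3"]), "x", 0.5),
            (nx.complete_graph(5), 0, 1 / 5),
            (nx.path_graph(["a", "b", "c"]), "b", 0.5),
        ],
    )
    def test_stationary_values(self, graph, item, expected):
        assert initial_item_prob(graph, item) == pytest.approx(expected)

    def test_sums_to_one(self):
        g = random_graph(7, 3)
        assert sum(initial_item_prob(g, v) for v in g) == pytest.approx(1.0)

    def test_absent_item_rejected(self, single_edge):
        with pytest.raises(ValueError):
            initial_item_prob(single_edge, "zebra")


class TestTransitionProb:
    def test_only_neighbour_is_certain(self, single_edge):
        for p in (0.0, 0.4, 1.0):
            assert transition_prob(["a"], "b", single_edge, p) == pytest.approx(1.0)

    def test_deterministic_censoring_forces_unique_absorber(self, path_bac):
        assert transition_prob(["b", "a"], "c", path_bac, 0.0) == pytest.approx(1.0)

    def test_closed_form_renewal_series(self, path_bac):
        # renewal-series values 2/7, 1/7, 4/7 (see module docstring)
        assert transition_prob(["b", "a"], "b", path_bac, 0.5) == pytest.approx(2 / 7)
        assert transition_prob(["b", "a"], "a", path_bac, 0.5) == pytest.approx(1 / 7)
        assert transition_prob(["b", "a"], "c", path_bac, 0.5) == pytest.approx(4 / 7)

    def test_pemit_zero_forbids_perseveration(self, path_bac):
        assert transition_prob(["b", "a"], "b", path_bac, 0.0) == 0.0

    def test_pemit_one_is_uncensored_walk(self, path_bac):
        # Q' = 0, E = I: next-emission distribution is the row of A
        dist = emission_distribution(path_bac, ["b", "a"], 1.0)
        assert dist == pytest.approx({"a": 0.0, "b": 0.5, "c": 0.5})

    def test_out_of_range_pemit_rejected(self, path_bac):
        with pytest.raises(ValueError):
            transition_prob(["b", "a"], "c", path_bac, 1.5)


class TestEmissionDistribution:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("p_emit", [0.0, 0.3, 0.7, 1.0])
    def test_completeness_over_all_nodes(self, seed, p_emit):
        """With every node a candidate, next-emission mass must total 1."""
        g = random_graph(6, seed)
        nodes = sorted(g)
        prefix = nodes[:4]  # any history works; the chain starts at its last element
        total = sum(emission_distribution(g, prefix, p_emit).values())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_substochastic_when_candidates_missing(self, path_bac):
        # likelihood of a specific list loses the mass of unlisted absorbers
        p_next = transition_prob(["a"], "b", path_bac, 0.5)
        assert p_next < 1.0  # c also absorbs


class TestListLogLikelihood:
    def test_single_edge_list(self, single_edge):
        fl = FluencyList("p", "l", ("a", "b"))
        assert list_log_likelihood(fl, single_edge, 0.3) == pytest.approx(math.log(0.5))

    def test_repeat_at_pemit_zero_impossible(self, single_edge):
        fl = FluencyList("p", "l", ("a", "b", "a"))
        assert list_log_likelihood(fl, single_edge, 0.0) == -math.inf

    def test_single_item_list_is_stationary(self, path_bac):
        fl = FluencyList("p", "l", ("a",))
        # a is the path centre: deg(a)=2, 2|E|=4
        assert list_log_likelihood(fl, path_bac, 0.5) == pytest.approx(math.log(0.5))

    def test_immediate_repeat_impossible_at_start(self, path_bac):
        # an immediate repeat with a single observed node cannot occur
        fl = FluencyList("p", "l", ("a", "a"))
        assert list_log_likelihood(fl, path_bac, 0.9) == -math.inf

    @pytest.mark.parametrize("seed", range(3))
    def test_relabelling_invariance(self, seed):
        g = random_graph(6, seed)
        corpus = simulate_corpus(g, 0.3, 4, 5, seed=seed + 50)
        mapping = {v: f"relab_{v}" for v in g}
        g2 = nx.relabel_nodes(g, mapping)
        ll1 = corpus_log_likelihood(corpus, g, 0.3)
        renamed = make_corpus(
            [[mapping[it] for it in fl.items] for fl in corpus.lists]
        )
        ll2 = corpus_log_likelihood(renamed, g2, 0.3)
        assert ll1 == pytest.approx(ll2, rel=1e-12)


class TestCorpusLogLikelihood:
    def test_single_list_equals_list_loglik(self, single_edge):
        fl = FluencyList("p", "l", ("a", "b"))
        corpus = make_corpus([["a", "b"]])
        assert corpus_log_likelihood(corpus, single_edge, 0.2) == pytest.approx(
            list_log_likelihood(fl, single_edge, 0.2)
        )

    def test_list_order_invariance(self, path_bac):
        c1 = make_corpus([["a", "b"], ["b", "a", "c"]])
        c2 = make_corpus([["b", "a", "c"], ["a", "b"]])
        assert corpus_log_likelihood(c1, path_bac, 0.4) == pytest.approx(
            corpus_log_likelihood(c2, path_bac, 0.4)
        )

    def test_duplicated_list_doubles_loglik(self, path_bac):
        one = make_corpus([["a", "b"]])
        two = make_corpus([["a", "b"], ["a", "b"]])
        assert corpus_log_likelihood(two, path_bac, 0.4) == pytest.approx(
            2 * corpus_log_likelihood(one, path_bac, 0.4)
        )

    def test_grid_matches_pointwise(self, path_bac):
        corpus = make_corpus([["a", "b", "a", "c"], ["c", "a", "b"]])
        grid = corpus_log_likelihood_grid(corpus, path_bac)
        for gi in (0, 13, 50, 100):
            expected = corpus_log_likelihood(corpus, path_bac, float(PEMIT_GRID[gi]))
            if math.isinf(expected):
                assert math.isinf(grid[gi])
            else:
                assert grid[gi] == pytest.approx(expected, rel=1e-10)


@pytest.mark.parametrize("p_emit", [0.3, 0.7])
def test_likelihood_matches_simulation_frequencies(p_emit, rng):
    """Quick Monte-Carlo agreement check (the full oracle runs in acceptance)."""
    from collections import Counter

    from fluencynet import WalkSimulator

    g = random_graph(4, 9, p=0.6)
    sim = WalkSimulator(g)
    n = 20000
    counts = Counter(tuple(sim.sample_emissions(p_emit, 3, rng)) for _ in range(n))
    checked = 0
    for seq, c in counts.most_common(8):
        fl = FluencyList("p", "l", seq)
        prob = math.exp(list_log_likelihood(fl, g, p_emit))
        se = math.sqrt(prob * (1 - prob) / n)
        assert abs(c / n - prob) <= 5 * se + 1e-9
        checked += 1
    assert checked > 0
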