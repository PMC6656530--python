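"""MAP search: posterior composition, p_emit grid fit, stochastic toggles."""

import math

import networkx as nx
import numpy as np
import pytest

from conftest import make_corpus, simulate_corpus
from fluencynet import (
    EdgePrior,
    EstimationError,
    edge_recovery_f1,
    estimate_network,
    exhaustive_map,
    fit_pemit,
    log_posterior,
    naive_network,
)
from fluencynet.estimator import LOG_PEMIT_GRID_PRIOR
from fluencynet.likelihood import corpus_log_likelihood
from fluencynet.prior import network_log_prior


class TestLogPosterior:
    def test_composition_on_single_edge(self, single_edge):
        corpus = make_corpus([["a", "b"]])
        prior = EdgePrior()
        expected = math.log(0.5) + math.log(0.5) + LOG_PEMIT_GRID_PRIOR
        assert log_posterior(single_edge, 0.3, corpus, prior) == pytest.approx(expected)

    def test_zero_likelihood_gives_neg_inf(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])  # no edges: walk undefined
        corpus = make_corpus([["a", "b"]])
        assert log_posterior(g, 0.3, corpus, EdgePrior()) == -math.inf

    def test_matches_component_sum_over_all_three_node_graphs(self, toy_corpus):
        prior = EdgePrior()
        from oracles import all_graphs

        for edges in all_graphs(["a", "b", "c"]):
            g = nx.Graph()
            g.add_nodes_from(["a", "b", "c"])
            g.add_edges_from(edges)
            direct = log_posterior(g, 0.25, toy_corpus, prior)
            parts = corpus_log_likelihood(toy_corpus, g, 0.25)
            if math.isinf(parts):
                assert direct == -math.inf
            else:
                assert direct == pytest.approx(
                    parts + network_log_prior(g, prior) + LOG_PEMIT_GRID_PRIOR
                )


class TestFitPemit:
    def test_repeat_free_corpus_fits_zero(self, path_bac):
        corpus = make_corpus([["b", "a", "c"], ["c", "a", "b"]])
        assert fit_pemit(path_bac, corpus) == 0.0

    def test_corpus_with_repeat_fits_positive(self, path_bac):
        corpus = make_corpus([["b", "a", "b", "c"]])
        assert fit_pemit(path_bac, corpus) > 0.0

    def test_recovery_from_simulated_lists(self, ws10):
        corpus = simulate_corpus(ws10, 0.4, 30, 15, seed=4)
        assert abs(fit_pemit(ws10, corpus) - 0.4) <= 0.1

    def test_all_neg_inf_raises(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        corpus = make_corpus([["a", "b"]])
        with pytest.raises(EstimationError):
            fit_pemit(g, corpus)


class TestEstimateNetwork:
    def test_two_node_corpus_recovers_only_edge(self):
        corpus = make_corpus([["a", "b"]] * 5)
        res = estimate_network(corpus, seed=0)
        assert sorted(res.network.edges()) == [("a", "b")]

    def test_same_seed_bit_identical(self, ws10):
        corpus = simulate_corpus(ws10, 0.2, 8, 10, seed=3)
        r1 = estimate_network(corpus, seed=11)
        r2 = estimate_network(corpus, seed=11)
        assert r1.trace == r2.trace
        assert r1.p_emit == r2.p_emit
        assert sorted(r1.network.edges()) == sorted(r2.network.edges())
        assert r1.log_posterior == r2.log_posterior

    def test_trace_is_strictly_increasing(self, ws10):
        corpus = simulate_corpus(ws10, 0.2, 8, 10, seed=3)
        res = estimate_network(corpus, seed=1)
        values = [v for _, v in res.trace]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_final_posterior_recomputable(self, ws10):
        corpus = simulate_corpus(ws10, 0.2, 8, 10, seed=3)
        res = estimate_network(corpus, seed=2)
        recomputed = log_posterior(res.network, res.p_emit, corpus, EdgePrior())
        assert res.log_posterior == pytest.approx(recomputed, abs=1e-9)

    def test_beats_naive_baseline_on_simulated_data(self, ws10):
        f1_est, f1_naive = [], []
        for seed in range(3):
            corpus = simulate_corpus(ws10, 0.2, 15, 12, seed=100 + seed)
            res = estimate_network(corpus, seed=seed)
            f1_est.append(edge_recovery_f1(res.network, ws10))
            f1_naive.append(edge_recovery_f1(naive_network(corpus), ws10))
        assert np.mean(f1_est) >= np.mean(f1_naive)

    def test_posterior_never_below_initial(self, ws10):
        corpus = simulate_corpus(ws10, 0.2, 8, 10, seed=3)
        res = estimate_network(corpus, seed=4)
        assert res.log_posterior >= res.trace[0][1]


class TestExhaustiveOracle:
    def test_search_attains_enumerated_optimum_most_seeds(self, toy_corpus):
        _, _, best_post = exhaustive_map(toy_corpus)
        hits = sum(
            math.isclose(
                estimate_network(toy_corpus, seed=seed).log_posterior,
                best_post,
                abs_tol=1e-6,
            )
            for seed in range(8)
        )
        assert hits >= 7

    def test_enumeration_rejects_large_vocab(self):
        corpus = make_corpus([[f"x{i}" for i in range(7)]])
        with pytest.raises(ValueError):
            exhaustive_map(corpus)


class TestEdgeRecoveryF1:
    def test_perfect_match(self, ws10):
        assert edge_recovery_f1(ws10, ws10) == 1.0

    def test_truth_restricted_to_estimated_nodes(self, path_bac):
        est = nx.Graph([("b", "a")])
        assert edge_recovery_f1(est, path_bac) == 1.0
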