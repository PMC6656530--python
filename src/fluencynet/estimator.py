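"""MAP estimation of a participant's semantic network and p_emit.

The posterior over (G, p_emit) combines the noisy censored random walk
likelihood of the participant's fluency corpus, the edge-wise network prior,
and a uniform prior over the 101-point p_emit grid.  The joint maximizer is
sought by greedy stochastic search over graphs with p_emit profiled out:
propose toggling one node pair, accept only if the candidate's best
posterior over the p_emit grid strictly exceeds the incumbent's, re-fit
p_emit by full grid search after every accepted toggle, and stop after
``patience`` (default 300) consecutive proposals fail to improve.

Search starts from the "naive" network linking every pair of items adjacent
in some list, which assigns finite likelihood to every observed transition
whenever p_emit > 0.  Proposals favour node pairs that co-occur within a
list (probability 1/2) but any pair can be proposed, so the chain can reach
every graph; toggles that would disconnect a used node are simply rejected
by their -inf likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .corpus import FluencyCorpus
from .errors import EstimationError
from .likelihood import (
    PEMIT_GRID,
    _ListStructure,
    _prepare_list,
    _transitions_loglik,
    _transitions_loglik_grid,
    corpus_log_likelihood,
    corpus_log_likelihood_grid,
)
from .prior import EdgePrior, network_log_prior

__all__ = [
    "EstimationResult",
    "log_posterior",
    "fit_pemit",
    "naive_network",
    "estimate_network",
    "exhaustive_map",
    "edge_recovery_f1",
]

#: log prior mass of any single grid value of p_emit (uniform over 101 points).
LOG_PEMIT_GRID_PRIOR = -math.log(len(PEMIT_GRID))

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class EstimationResult:
    """MAP network, fitted p_emit, and the accepted-toggle trace."""

    network: nx.Graph
    p_emit: float
    log_posterior: float
    trace: tuple[tuple[int, float], ...]
    seed: int
    converged: bool
    n_proposals: int
    n_accepted: int


def log_posterior(
    net: nx.Graph, p_emit: float, corpus: FluencyCorpus, prior: EdgePrior
) -> float:
    """Unnormalized log posterior log P(G, p_emit | X) (up to a constant)."""
    ll = corpus_log_likelihood(corpus, net, p_emit)
    if ll == _NEG_INF:
        return _NEG_INF
    return ll + network_log_prior(net, prior) + LOG_PEMIT_GRID_PRIOR


def fit_pemit(net: nx.Graph, corpus: FluencyCorpus) -> float:
    """Grid value of p_emit maximizing the corpus likelihood given ``net``.

    Ties break toward the smaller value.  Raises :class:`EstimationError`
    when every grid value scores -inf.
    """
    lls = corpus_log_likelihood_grid(corpus, net)
    if not np.any(np.isfinite(lls)):
        raise EstimationError("corpus has zero likelihood at every p_emit grid value")
    return float(PEMIT_GRID[int(np.argmax(lls))])


def naive_network(corpus: FluencyCorpus) -> nx.Graph:
    """Graph linking every pair of items adjacent in any list."""
    g = nx.Graph()
    g.add_nodes_from(corpus.vocabulary)
    for fl in corpus.lists:
        for a, b in zip(fl.items, fl.items[1:]):
            if a != b:
                g.add_edge(a, b)
    return g


class _SearchState:
    """Incremental posterior bookkeeping for the toggle search.

    Per-list transition log-likelihood *grid vectors* are cached; a toggle of
    pair (i, j) only invalidates lists whose unique-item set touches i or j.
    The global stationary normalizer log 2|E| is kept separate because every
    toggle changes it for every list.
    """

    def __init__(self, corpus: FluencyCorpus, prior: EdgePrior, init: nx.Graph):
        self.vocab = sorted(corpus.vocabulary)
        self.m_nodes = len(self.vocab)
        index = {v: i for i, v in enumerate(self.vocab)}
        self.lists = [
            np.fromiter((index[it] for it in fl.items), dtype=np.intp, count=len(fl))
            for fl in corpus.lists
        ]
        self.structs = [_prepare_list(arr) for arr in self.lists]
        self.n_lists = len(self.lists)
        self.contains = np.zeros((self.n_lists, self.m_nodes), dtype=bool)
        for li, arr in enumerate(self.lists):
            self.contains[li, np.unique(arr)] = True
        # log prior per pair, edge present / absent
        m = self.m_nodes
        self.lp1 = np.zeros((m, m))
        self.lp0 = np.zeros((m, m))
        for i, j in combinations(range(m), 2):
            p = prior.edge_prob(self.vocab[i], self.vocab[j])
            self.lp1[i, j] = self.lp1[j, i] = math.log(p)
            self.lp0[i, j] = self.lp0[j, i] = math.log1p(-p)
        self.adj = np.zeros((m, m), dtype=bool)
        for u, v in init.edges():
            iu, iv = index[u], index[v]
            if iu != iv:
                self.adj[iu, iv] = self.adj[iv, iu] = True
        self.deg = self.adj.sum(axis=1).astype(float)
        self.n_edges = float(self.deg.sum() / 2.0)
        self.a = self._kernel(self.adj, self.deg)
        iu, jv = np.triu_indices(m, k=1)
        self.prior_val = float(
            np.sum(np.where(self.adj[iu, jv], self.lp1[iu, jv], self.lp0[iu, jv]))
        )
        # proposal screening evaluates candidates on a coarse p_emit subgrid
        # (every 0.05); accepted toggles are always re-fitted on the full grid
        self.screen_idx = np.arange(0, len(PEMIT_GRID), 5)
        # per-list grid vectors: log deg(x1) + transition log-lik at each grid p
        self.cvec = np.zeros((self.n_lists, len(PEMIT_GRID)))
        for li in range(self.n_lists):
            self.cvec[li] = self._list_cvec(self.a, self.deg, self.lists[li], self.structs[li])
        self.g_cur = self._refit()

    @staticmethod
    def _kernel(adj: np.ndarray, deg: np.ndarray) -> np.ndarray:
        safe = np.where(deg > 0, deg, 1.0)
        return adj.astype(float) / safe[:, None]

    @staticmethod
    def _list_cvec(
        a: np.ndarray, deg: np.ndarray, items: np.ndarray, struct: _ListStructure
    ) -> np.ndarray:
        d = deg[items[0]]
        if d == 0:
            return np.full(len(PEMIT_GRID), _NEG_INF)
        return math.log(d) + _transitions_loglik_grid(a, struct, PEMIT_GRID)

    def _totals(self) -> np.ndarray:
        if self.n_edges == 0:
            return np.full(len(PEMIT_GRID), _NEG_INF)
        return self.cvec.sum(axis=0) - self.n_lists * math.log(2.0 * self.n_edges)

    def _refit(self) -> int:
        """Grid index maximizing the current total likelihood (ties -> smaller p)."""
        return int(np.argmax(self._totals()))

    @property
    def p_emit(self) -> float:
        return float(PEMIT_GRID[self.g_cur])

    @property
    def log_post(self) -> float:
        total = self._totals()[self.g_cur]
        if total == _NEG_INF:
            return _NEG_INF
        return float(total + self.prior_val + LOG_PEMIT_GRID_PRIOR)

    def _candidate_arrays(self, i: int, j: int):
        adding = not self.adj[i, j]
        delta = 1.0 if adding else -1.0
        deg_c = self.deg.copy()
        deg_c[i] += delta
        deg_c[j] += delta
        adj_c = self.adj.copy()
        adj_c[i, j] = adj_c[j, i] = adding
        a_c = self.a.copy()
        for node in (i, j):
            if deg_c[node] > 0:
                a_c[node] = adj_c[node] / deg_c[node]
            else:
                a_c[node] = 0.0
        dprior = (self.lp1[i, j] - self.lp0[i, j]) * (1.0 if adding else -1.0)
        return adj_c, deg_c, a_c, self.n_edges + delta, dprior

    def evaluate_toggle(self, i: int, j: int) -> float:
        """Screening posterior of the toggled graph.

        The joint argmax over (G, p_emit) is searched by profiling p_emit out
        of the acceptance decision; otherwise the search can wedge in basins
        where the incumbent p_emit makes every single toggle look worse.  A
        cheap evaluation at the incumbent p_emit short-circuits the common
        case of an improving toggle; otherwise the candidate is profiled over
        a coarse subgrid of p_emit (every 0.05, plus the incumbent).  Accepts
        are therefore always sound (any grid point is a lower bound on the
        profile maximum); an improving toggle whose advantage exists only
        between screening points can be missed on this pass, but becomes
        eligible again after the next acceptance.
        """
        adj_c, deg_c, a_c, m_c, dprior = self._candidate_arrays(i, j)
        if m_c == 0:
            return _NEG_INF
        affected = np.flatnonzero(self.contains[:, i] | self.contains[:, j])
        log_2m = math.log(2.0 * m_c)
        if self.log_post > _NEG_INF:
            p = self.p_emit
            col = self.cvec[:, self.g_cur]
            # current posterior is finite here, so every cached entry is finite
            ll = float(col.sum() - col[affected].sum())
            shortcut_ok = True
            for li in affected:
                d = deg_c[self.lists[li][0]]
                tl = _NEG_INF if d == 0 else _transitions_loglik(a_c, self.structs[li], p)
                if tl == _NEG_INF:
                    shortcut_ok = False
                    break
                ll += math.log(d) + tl
            if shortcut_ok:
                cand = ll - self.n_lists * log_2m + dprior + self.prior_val
                cand += LOG_PEMIT_GRID_PRIOR
                if cand > self.log_post:
                    return float(cand)
        # coarse profile of the candidate over p_emit
        screen = np.unique(np.append(self.screen_idx, self.g_cur))
        grid = PEMIT_GRID[screen]
        keep = np.ones(self.n_lists, dtype=bool)
        keep[affected] = False
        # summed as -inf-safe additions (never subtract -inf from -inf)
        total = self.cvec[keep][:, screen].sum(axis=0) if keep.any() else np.zeros(len(screen))
        for li in affected:
            d = deg_c[self.lists[li][0]]
            if d == 0:
                return _NEG_INF
            total = total + math.log(d) + _transitions_loglik_grid(
                a_c, self.structs[li], grid
            )
        total = total - self.n_lists * log_2m
        best = float(np.max(total))
        if best == _NEG_INF:
            return _NEG_INF
        return best + dprior + self.prior_val + LOG_PEMIT_GRID_PRIOR

    def commit(self, i: int, j: int) -> None:
        adj_c, deg_c, a_c, m_c, dprior = self._candidate_arrays(i, j)
        self.adj, self.deg, self.a, self.n_edges = adj_c, deg_c, a_c, m_c
        self.prior_val += dprior
        affected = np.flatnonzero(self.contains[:, i] | self.contains[:, j])
        for li in affected:
            self.cvec[li] = self._list_cvec(self.a, self.deg, self.lists[li], self.structs[li])
        self.g_cur = self._refit()

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vocab)
        for i, j in zip(*np.nonzero(np.triu(self.adj, k=1))):
            g.add_edge(self.vocab[i], self.vocab[j])
        return g


def _cooccurring_pairs(state: _SearchState) -> list[tuple[int, int]]:
    pairs = set()
    for arr in state.lists:
        uniq = np.unique(arr)
        for a, b in combinations(uniq.tolist(), 2):
            pairs.add((a, b))
    return sorted(pairs)


def estimate_network(
    corpus: FluencyCorpus,
    prior: EdgePrior | None = None,
    *,
    seed: int = 0,
    patience: int = 300,
    max_iters: int = 20000,
    initial: nx.Graph | None = None,
) -> EstimationResult:
    """Greedy stochastic MAP search over (G, p_emit) for one participant.

    Deterministic given ``seed`` and input.  ``converged`` is True when the
    search stopped because ``patience`` consecutive proposals failed to
    improve the posterior (rather than by hitting ``max_iters``).
    """
    prior = prior if prior is not None else EdgePrior()
    rng = np.random.default_rng(seed)
    init = initial if initial is not None else naive_network(corpus)
    if set(init.nodes()) != set(corpus.vocabulary):
        raise ValueError("initial network must have exactly the corpus vocabulary as nodes")
    state = _SearchState(corpus, prior, init)
    m = state.m_nodes
    cooc = _cooccurring_pairs(state)
    trace: list[tuple[int, float]] = [(0, state.log_post)]
    fails = 0
    n_acc = 0
    proposals = 0
    converged = False
    rejected: set[tuple[int, int]] = set()  # pairs already screened since last accept
    if m >= 2:
        while proposals < max_iters:
            proposals += 1
            if cooc and rng.random() < 0.5:
                i, j = cooc[int(rng.integers(len(cooc)))]
            else:
                i = int(rng.integers(m))
                j = int(rng.integers(m - 1))
                if j >= i:
                    j += 1
                i, j = min(i, j), max(i, j)
            if (i, j) in rejected:
                cand_post = _NEG_INF  # unchanged graph and incumbent: same verdict
            else:
                cand_post = state.evaluate_toggle(i, j)
            if cand_post > state.log_post:
                state.commit(i, j)
                n_acc += 1
                fails = 0
                rejected.clear()
                trace.append((proposals, state.log_post))
            else:
                rejected.add((i, j))
                fails += 1
                if fails >= patience:
                    converged = True
                    break
    else:
        converged = True
    final_post = state.log_post
    if final_post == _NEG_INF:
        raise EstimationError(
            "no network with finite posterior found within the proposal budget"
        )
    return EstimationResult(
        network=state.to_graph(),
        p_emit=state.p_emit,
        log_posterior=final_post,
        trace=tuple(trace),
        seed=int(seed),
        converged=converged,
        n_proposals=proposals,
        n_accepted=n_acc,
    )


def exhaustive_map(
    corpus: FluencyCorpus, prior: EdgePrior | None = None, max_nodes: int = 5
) -> tuple[nx.Graph, float, float]:
    """Global MAP by enumerating every graph on the vocabulary x the p grid.

    Only feasible for tiny vocabularies (2^(M choose 2) graphs); intended as
    an oracle for validating the stochastic search.
    Returns (best graph, best p_emit, best log posterior).
    """
    prior = prior if prior is not None else EdgePrior()
    vocab = sorted(corpus.vocabulary)
    if len(vocab) > max_nodes:
        raise ValueError(f"exhaustive enumeration limited to {max_nodes} nodes")
    pairs = list(combinations(vocab, 2))
    best = (None, None, _NEG_INF)
    for mask in range(2 ** len(pairs)):
        g = nx.Graph()
        g.add_nodes_from(vocab)
        g.add_edges_from(p for b, p in enumerate(pairs) if mask >> b & 1)
        lls = corpus_log_likelihood_grid(corpus, g)
        if not np.any(np.isfinite(lls)):
            continue
        gi = int(np.argmax(lls))
        post = float(lls[gi]) + network_log_prior(g, prior) + LOG_PEMIT_GRID_PRIOR
        if post > best[2]:
            best = (g, float(PEMIT_GRID[gi]), post)
    if best[0] is None:
        raise EstimationError("no graph on the vocabulary has finite posterior")
    return best  # type: ignore[return-value]


def edge_recovery_f1(estimated: nx.Graph, truth: nx.Graph) -> float:
    """F1 of the estimated edge set against the truth, over the estimated node set.

    The truth is restricted to the nodes the participant actually produced,
    since unlisted concepts are invisible to the estimator.
    """
    nodes = set(estimated.nodes())
    est = {tuple(sorted(e)) for e in estimated.edges()}
    true = {
        tuple(sorted(e))
        for e in truth.edges()
        if e[0] in nodes and e[1] in nodes
    }
    tp = len(est & true)
    fp = len(est - true)
    fn = len(true - est)
    if 2 * tp + fp + fn == 0:
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)
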