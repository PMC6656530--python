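"""Exact likelihood of fluency lists under a noisy censored random walk.

The retrieval model assumes a participant produces a fluency list by walking
randomly on their semantic network G: from node i the walker moves to a
uniformly random neighbour.  Nodes are *emitted* (spoken) on first visit;
revisits are emitted with probability ``p_emit`` (a perseveration) and
silently censored otherwise.  The first item of a list is assumed drawn from
the stationary distribution of the walk, deg(i) / 2|E|.

Each subsequent emission is the absorption event of an absorbing Markov
chain.  Let the unique items observed so far (s of them) be the transient
states, with sub-transition matrix Q taken from the full row-stochastic
matrix A (A_ij = G_ij / deg(i)).  Censored wandering among observed nodes
happens with probability (1 - p_emit) per step, so the transient kernel is
Q' = (1 - p_emit) Q.  Absorption happens by re-emitting an observed node
(probability p_emit per visit; columns p_emit * Q) or by hitting an unvisited
node (columns of A into the complement).  With the fundamental matrix
E = (I - Q')^-1, the probability that the next emission is item i given the
walker sits at the last emitted item j is  sum_k E_jk R'_ki,  and 0 when
(I - Q') is singular.

Mass flowing to nodes outside a list's unique-item set corresponds to
emitting an item that is not in this list, so per-list transition
distributions are sub-stochastic unless the list covers the whole network.
Impossible data score exactly ``-inf`` (never a large negative sentinel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .corpus import FluencyCorpus, FluencyList

__all__ = [
    "PEMIT_GRID",
    "TransitionMatrix",
    "build_transition_matrix",
    "initial_item_prob",
    "transition_prob",
    "emission_distribution",
    "list_log_likelihood",
    "corpus_log_likelihood",
    "corpus_log_likelihood_grid",
]

#: The 101-point grid over which p_emit is fitted, {0.00, 0.01, ..., 1.00}.
PEMIT_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)

# Linear solves whose residual exceeds this are treated as singular systems,
# mapping the transition probability to 0 ("0 otherwise").
_SINGULAR_TOL = 1e-8

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic walk kernel of a semantic network.

    ``matrix[i, j] = G_ij / deg(i)``; rows of isolated nodes are all-zero and
    the nodes are reported in :attr:`isolated` rather than silently dropped.
    """

    nodes: tuple[str, ...]
    index: Mapping[str, int]
    matrix: np.ndarray
    degrees: np.ndarray
    n_edges: int
    isolated: frozenset[str]


def build_transition_matrix(net: nx.Graph) -> TransitionMatrix:
    """Translate an undirected link matrix into the walk kernel A."""
    nodes = tuple(sorted(net.nodes()))
    if not nodes:
        raise ValueError("cannot build a transition matrix for an empty network")
    index = {v: i for i, v in enumerate(nodes)}
    adj = nx.to_numpy_array(net, nodelist=nodes, dtype=float)
    np.fill_diagonal(adj, 0.0)
    adj = (adj > 0).astype(float)  # unweighted
    deg = adj.sum(axis=1)
    safe = np.where(deg > 0, deg, 1.0)
    a = adj / safe[:, None]
    isolated = frozenset(nodes[i] for i in np.flatnonzero(deg == 0))
    return TransitionMatrix(nodes, index, a, deg, int(round(deg.sum() / 2)), isolated)


def _check_pemit(p_emit: float) -> float:
    p = float(p_emit)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p_emit must lie in [0, 1], got {p_emit!r}")
    return p


def _to_indices(items: Sequence[str], index: Mapping[str, int], what: str) -> np.ndarray:
    try:
        return np.fromiter((index[it] for it in items), dtype=np.intp, count=len(items))
    except KeyError as exc:
        raise ValueError(f"{what} item {exc.args[0]!r} is not a node of the network") from None


def initial_item_prob(net: nx.Graph, item: str) -> float:
    """Stationary probability deg(item) / 2|E| of the list's first item."""
    tm = build_transition_matrix(net)
    if item not in tm.index:
        raise ValueError(f"item {item!r} is not a node of the network")
    if tm.n_edges == 0:
        raise ValueError("the network has no edges; the walk is undefined")
    return float(tm.degrees[tm.index[item]] / (2.0 * tm.n_edges))


def _fundamental_row(q: np.ndarray, s: int, j: int, p_emit: float) -> np.ndarray | None:
    """Row j of E = (I - (1-p)Q)^-1, or ``None`` when the system is singular."""
    t = np.eye(s) - (1.0 - p_emit) * q[:s, :s]
    e = np.zeros(s)
    e[j] = 1.0
    try:
        y = np.linalg.solve(t.T, e)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(y)):
        return None
    if np.abs(t.T @ y - e).max() > _SINGULAR_TOL:
        return None
    return y


def _first_occurrence(items: np.ndarray) -> tuple[list[int], dict[int, int]]:
    uniq: list[int] = []
    pos: dict[int, int] = {}
    for it in items:
        it = int(it)
        if it not in pos:
            pos[it] = len(uniq)
            uniq.append(it)
    return uniq, pos


@dataclass(frozen=True)
class _ListStructure:
    """Graph-independent geometry of one list's transition computations.

    Precomputed once per list so repeated likelihood evaluations (stochastic
    search, p_emit grids) reduce to one batched linear solve.  For every
    transition n: ``s`` observed unique items form the transient block, ``j``
    is the walker's position (last emitted item), ``k`` the target column,
    and ``persev`` marks re-emissions.
    """

    uniq: np.ndarray        # (u,) node indices in first-occurrence order
    n_transitions: int
    j_arr: np.ndarray       # (n_t,) start position within uniq
    k_arr: np.ndarray       # (n_t,) target position within uniq
    s_arr: np.ndarray       # (n_t,) transient block size
    persev: np.ndarray      # (n_t,) bool, target already observed
    row_mask: np.ndarray    # (n_t, u) float, 1.0 where index < s
    blk_mask: np.ndarray    # (n_t, u, u) float, outer product of row_mask
    rhs: np.ndarray         # (n_t, u) basis vector e_j per transition


def _prepare_list(items: np.ndarray) -> _ListStructure:
    uniq, pos = _first_occurrence(items)
    u = len(uniq)
    n_t = len(items) - 1
    j_arr = np.empty(n_t, dtype=np.intp)
    k_arr = np.empty(n_t, dtype=np.intp)
    s_arr = np.empty(n_t, dtype=np.intp)
    persev = np.zeros(n_t, dtype=bool)
    seen = 1
    for n in range(1, len(items)):
        j_arr[n - 1] = pos[int(items[n - 1])]
        k = pos[int(items[n])]
        k_arr[n - 1] = k
        s_arr[n - 1] = seen
        if k < seen:
            persev[n - 1] = True
        else:
            seen += 1
    idx = np.arange(u)
    row_mask = (idx[None, :] < s_arr[:, None]).astype(float)
    blk_mask = row_mask[:, :, None] * row_mask[:, None, :]
    rhs = np.zeros((n_t, u))
    rhs[np.arange(n_t), j_arr] = 1.0
    return _ListStructure(
        np.asarray(uniq, dtype=np.intp), n_t, j_arr, k_arr, s_arr, persev,
        row_mask, blk_mask, rhs,
    )


def _transitions_scalar(au: np.ndarray, ls: _ListStructure, p_emit: float) -> float:
    """Transition-by-transition path; required at p_emit = 0 where (I - Q)
    can be genuinely singular (probability 0 by convention)."""
    total = 0.0
    for t in range(ls.n_transitions):
        s = int(ls.s_arr[t])
        y = _fundamental_row(au, s, int(ls.j_arr[t]), p_emit)
        if y is None:
            return _NEG_INF
        prob = float(y @ au[:s, ls.k_arr[t]])
        if ls.persev[t]:
            prob *= p_emit
        if prob <= 0.0 or not math.isfinite(prob):
            return _NEG_INF
        total += math.log(min(prob, 1.0))
    return total


def _transitions_loglik(a: np.ndarray, ls: _ListStructure, p_emit: float) -> float:
    """Sum of log transition probabilities of one list at one p_emit.

    For p_emit > 0 the transient kernel (1 - p)Q has spectral radius < 1, so
    I - Q' is never singular and all transitions solve in one batched call.
    """
    if ls.n_transitions == 0:
        return 0.0
    au = a[np.ix_(ls.uniq, ls.uniq)]
    if p_emit == 0.0:
        if ls.persev.any():  # deterministic censoring forbids repeats
            return _NEG_INF
        return _transitions_scalar(au, ls, 0.0)
    t_mats = np.eye(len(ls.uniq))[None, :, :] - (1.0 - p_emit) * (au[None, :, :] * ls.blk_mask)
    y = np.linalg.solve(t_mats.transpose(0, 2, 1), ls.rhs[:, :, None])[:, :, 0]
    cols = au[:, ls.k_arr].T * ls.row_mask
    prob = np.einsum("ti,ti->t", y, cols)
    prob[ls.persev] *= p_emit
    prob = np.clip(prob, 0.0, 1.0)
    if np.any(prob <= 0.0):
        return _NEG_INF
    return float(np.log(prob).sum())


def _transitions_loglik_grid(
    a: np.ndarray, ls: _ListStructure, grid: np.ndarray
) -> np.ndarray:
    """Transition log-likelihood sums of one list, one entry per grid p_emit."""
    n_grid = len(grid)
    out = np.zeros(n_grid)
    if ls.n_transitions == 0:
        return out
    au = a[np.ix_(ls.uniq, ls.uniq)]
    positive = grid > 0.0
    for gi in np.flatnonzero(~positive):
        out[gi] = (
            _NEG_INF if ls.persev.any() else _transitions_scalar(au, ls, 0.0)
        )
    gpos = grid[positive]
    if gpos.size:
        u = len(ls.uniq)
        base = au[None, :, :] * ls.blk_mask  # (n_t, u, u)
        t_mats = np.eye(u)[None, None, :, :] - (1.0 - gpos)[:, None, None, None] * base[None]
        t_mats = t_mats.reshape(-1, u, u).transpose(0, 2, 1)
        rhs = np.broadcast_to(ls.rhs[None], (len(gpos), ls.n_transitions, u)).reshape(-1, u)
        y = np.linalg.solve(np.ascontiguousarray(t_mats), rhs[:, :, None])[:, :, 0]
        y = y.reshape(len(gpos), ls.n_transitions, u)
        cols = au[:, ls.k_arr].T * ls.row_mask
        prob = np.einsum("gti,ti->gt", y, cols)
        prob[:, ls.persev] *= gpos[:, None]
        prob = np.clip(prob, 0.0, 1.0)
        with np.errstate(divide="ignore"):
            logs = np.where(prob > 0.0, np.log(np.where(prob > 0.0, prob, 1.0)), _NEG_INF)
        out[positive] = logs.sum(axis=1)
    return out


def _list_transitions_loglik(a: np.ndarray, items: np.ndarray, p_emit: float) -> float:
    return _transitions_loglik(a, _prepare_list(items), p_emit)


def _list_transitions_loglik_grid(
    a: np.ndarray, items: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    return _transitions_loglik_grid(a, _prepare_list(items), grid)


def transition_prob(
    list_prefix: Sequence[str], next_item: str, net: nx.Graph, p_emit: float
) -> float:
    """Probability that the next *emitted* item is ``next_item``.

    ``list_prefix`` holds the items emitted so far (repeats allowed); the walk
    starts at the last emitted item.  ``next_item`` may be a new node or a
    repeat of a previously observed one (a perseveration).  Returns 0 when
    (I - Q') is singular or the item is unreachable.
    """
    p = _check_pemit(p_emit)
    if len(list_prefix) == 0:
        raise ValueError("list_prefix must contain at least one emitted item")
    dist = emission_distribution(net, list_prefix, p)
    if next_item not in dist:
        raise ValueError(f"next_item {next_item!r} is not a node of the network")
    return dist[next_item]


def emission_distribution(
    net: nx.Graph, list_prefix: Sequence[str], p_emit: float
) -> dict[str, float]:
    """Distribution of the next emission over every node of the network.

    Observed nodes get their perseveration re-emission probability; unvisited
    nodes get their first-visit absorption probability.  The values sum to 1
    whenever absorption is certain (e.g. connected graph, prefix not covering
    every node), and to < 1 only through numerically singular systems.
    """
    p = _check_pemit(p_emit)
    tm = build_transition_matrix(net)
    prefix_idx = _to_indices(list(list_prefix), tm.index, "prefix")
    uniq, pos = _first_occurrence(prefix_idx)
    s = len(uniq)
    j = pos[int(prefix_idx[-1])]
    q = tm.matrix[np.ix_(uniq, uniq)]
    y = _fundamental_row(q, s, j, p)
    out = {node: 0.0 for node in tm.nodes}
    if y is None:
        return out
    persev = p * (y @ q)  # columns p_emit * Q
    for k, node_idx in enumerate(uniq):
        out[tm.nodes[node_idx]] = max(float(persev[k]), 0.0)
    observed = set(uniq)
    new_cols = [i for i in range(len(tm.nodes)) if i not in observed]
    if new_cols:
        absorb = y @ tm.matrix[np.ix_(uniq, new_cols)]
        for col, node_idx in enumerate(new_cols):
            out[tm.nodes[node_idx]] = max(float(absorb[col]), 0.0)
    return out


def list_log_likelihood(fluency_list: FluencyList, net: nx.Graph, p_emit: float) -> float:
    """Log-probability of one list: initial-item term plus all transitions."""
    p = _check_pemit(p_emit)
    tm = build_transition_matrix(net)
    items = _to_indices(fluency_list.items, tm.index, "list")
    return _list_loglik_from_tm(tm, items, p)


def _initial_logprob(tm: TransitionMatrix, first: int) -> float:
    if tm.n_edges == 0 or tm.degrees[first] == 0:
        return _NEG_INF
    return math.log(tm.degrees[first]) - math.log(2.0 * tm.n_edges)


def _list_loglik_from_tm(tm: TransitionMatrix, items: np.ndarray, p_emit: float) -> float:
    init = _initial_logprob(tm, int(items[0]))
    if init == _NEG_INF:
        return _NEG_INF
    trans = _list_transitions_loglik(tm.matrix, items, p_emit)
    return init + trans


def corpus_log_likelihood(corpus: FluencyCorpus, net: nx.Graph, p_emit: float) -> float:
    """Sum of per-list log-likelihoods (order of lists is immaterial)."""
    p = _check_pemit(p_emit)
    tm = build_transition_matrix(net)
    total = 0.0
    for fl in corpus.lists:
        items = _to_indices(fl.items, tm.index, "list")
        ll = _list_loglik_from_tm(tm, items, p)
        if ll == _NEG_INF:
            return _NEG_INF
        total += ll
    return total


def corpus_log_likelihood_grid(
    corpus: FluencyCorpus, net: nx.Graph, grid: np.ndarray | None = None
) -> np.ndarray:
    """Corpus log-likelihood evaluated at every grid value of p_emit at once."""
    grid = PEMIT_GRID if grid is None else np.asarray(grid, dtype=float)
    tm = build_transition_matrix(net)
    total = np.zeros(len(grid))
    for fl in corpus.lists:
        items = _to_indices(fl.items, tm.index, "list")
        init = _initial_logprob(tm, int(items[0]))
        if init == _NEG_INF:
            total[:] = _NEG_INF
            return total
        total += init + _list_transitions_loglik_grid(tm.matrix, items, grid)
    return total
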