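"""Network measures, small-world coefficient, mock ensembles and deltas.

Participant networks estimated from more (or longer) fluency lists have more
nodes and edges, which confounds raw comparisons of most graph measures.
The *mock ensemble* is the size-matched null model used to correct this:
each replicate permutes the item order within every list, re-estimates a
network with identical settings, and measures it.  A participant's *delta*
for a measure is their value minus the mock mean — how far the real,
sequentially structured data pull the estimate away from what arbitrary
orderings of the same items would give.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median

import networkx as nx
import numpy as np

from .corpus import FluencyCorpus, FluencyList
from .errors import EstimationError, UndefinedMeasureError
from .estimator import estimate_network
from .prior import EdgePrior

__all__ = [
    "MeasureSet",
    "compute_measures",
    "smallworld_coefficient",
    "MockEnsemble",
    "mock_ensemble",
    "delta_measures",
    "DELTA_MEASURES",
]

#: Measures corrected by the mock ensemble. Small-worldness is already a
#: ratio against size-matched random graphs and p_emit does not scale with
#: network size, so neither needs a correction.
DELTA_MEASURES = ("diameter", "density", "mean_degree", "median_degree", "aspl", "clustering")


@dataclass(frozen=True)
class MeasureSet:
    """Standard descriptive measures of one undirected network.

    ``diameter`` and ``aspl`` are computed on the largest connected component
    (they are undefined across components) and are NaN for single-node
    graphs.  ``clustering`` is global transitivity, 3·triangles / connected
    triplets.
    """

    n_nodes: int
    n_edges: int
    density: float
    diameter: float
    aspl: float
    mean_degree: float
    median_degree: float
    clustering: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "diameter": self.diameter,
            "aspl": self.aspl,
            "mean_degree": self.mean_degree,
            "median_degree": self.median_degree,
            "clustering": self.clustering,
        }


def _largest_component(net: nx.Graph) -> nx.Graph:
    comp = max(nx.connected_components(net), key=len)
    return net.subgraph(comp)


def compute_measures(net: nx.Graph) -> MeasureSet:
    """Compute the full measure set for one network."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("cannot measure an empty network")
    m = net.number_of_edges()
    degrees = [d for _, d in net.degree()]
    lcc = _largest_component(net)
    if lcc.number_of_nodes() >= 2:
        diameter = float(nx.diameter(lcc))
        aspl = float(nx.average_shortest_path_length(lcc))
    else:
        diameter = math.nan
        aspl = math.nan
    density = float(nx.density(net)) if n > 1 else math.nan
    return MeasureSet(
        n_nodes=n,
        n_edges=m,
        density=density,
        diameter=diameter,
        aspl=aspl,
        mean_degree=2.0 * m / n,
        median_degree=float(median(degrees)),
        clustering=float(nx.transitivity(net)),
    )


def smallworld_coefficient(
    net: nx.Graph, n_random: int = 100, rng: np.random.Generator | None = None
) -> float:
    """Small-world coefficient (C/C_rand) / (L/L_rand).

    C is global transitivity and L the average shortest-path length of the
    largest component; C_rand and L_rand are means over ``n_random``
    Erdős–Rényi G(n, m) graphs matched in node and edge count (the same
    largest-component convention applies to each).  Values above 1 indicate
    small-world structure.
    """
    rng = np.random.default_rng() if rng is None else rng
    lcc = _largest_component(net)
    if lcc.number_of_nodes() < 3:
        raise UndefinedMeasureError("small-worldness needs a largest component of >= 3 nodes")
    n = net.number_of_nodes()
    m = net.number_of_edges()
    c = float(nx.transitivity(net))
    length = float(nx.average_shortest_path_length(lcc))
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    for r in range(n_random):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1)))
        c_rand[r] = nx.transitivity(g)
        g_lcc = _largest_component(g)
        l_rand[r] = (
            nx.average_shortest_path_length(g_lcc) if g_lcc.number_of_nodes() >= 2 else np.nan
        )
    c_bar = float(np.nanmean(c_rand))
    l_bar = float(np.nanmean(l_rand))
    if c_bar == 0 or not np.isfinite(l_bar) or l_bar == 0:
        raise UndefinedMeasureError(
            "random baseline has no triangles or no paths; coefficient undefined"
        )
    return (c / c_bar) / (length / l_bar)


@dataclass(frozen=True)
class MockEnsemble:
    """Measures of k networks re-estimated from within-list permutations."""

    measures: tuple[MeasureSet, ...]
    p_emits: tuple[float, ...]
    seeds: tuple[int, ...]
    n_failed: int

    def mean(self, field: str) -> float:
        values = np.array([getattr(ms, field) for ms in self.measures], dtype=float)
        if values.size == 0 or np.all(np.isnan(values)):
            return math.nan
        return float(np.nanmean(values))

    @property
    def mean_p_emit(self) -> float:
        return float(np.mean(self.p_emits)) if self.p_emits else math.nan


def mock_ensemble(
    corpus: FluencyCorpus,
    prior: EdgePrior | None = None,
    *,
    k: int = 50,
    rng: np.random.Generator | None = None,
    estimator_config: dict | None = None,
) -> MockEnsemble:
    """Estimate ``k`` mock networks from within-list permutations of ``corpus``.

    Permutations shuffle item order inside each list only; list membership
    and lengths are preserved, so every mock network has exactly the
    participant's M nodes.  Replicates whose estimation fails are excluded
    from the means (and counted) rather than retried.
    """
    rng = np.random.default_rng() if rng is None else rng
    cfg = dict(estimator_config or {})
    cfg.pop("seed", None)
    out_measures: list[MeasureSet] = []
    out_pemits: list[float] = []
    seeds: list[int] = []
    n_failed = 0
    for r in range(k):
        perm_lists = []
        for fl in corpus.lists:
            order = rng.permutation(len(fl.items))
            perm_lists.append(
                FluencyList(fl.participant_id, f"{fl.list_id}#perm{r}",
                            tuple(fl.items[i] for i in order))
            )
        seed_r = int(rng.integers(2**31 - 1))
        seeds.append(seed_r)
        mock_corpus = FluencyCorpus(corpus.participant_id, tuple(perm_lists))
        try:
            res = estimate_network(mock_corpus, prior, seed=seed_r, **cfg)
        except EstimationError:
            n_failed += 1
            continue
        out_measures.append(compute_measures(res.network))
        out_pemits.append(res.p_emit)
    return MockEnsemble(tuple(out_measures), tuple(out_pemits), tuple(seeds), n_failed)


def delta_measures(participant: MeasureSet, ensemble: MockEnsemble) -> dict[str, float]:
    """Participant measure minus mock mean, for each size-confounded measure."""
    if len(ensemble.measures) == 0:
        return {f: math.nan for f in DELTA_MEASURES}
    return {f: getattr(participant, f) - ensemble.mean(f) for f in DELTA_MEASURES}
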