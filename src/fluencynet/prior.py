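"""Edge-wise network prior anchored to a reference association network.

The prior treats every unordered node pair independently.  A pair that is an
edge of the reference network (typically built from free-association norms,
e.g. the USF animal cue–response pairs) has prior edge probability 2/3; a
pair whose two labels both occur in the reference but are not adjacent has
probability 0.4; a pair with at least one label unknown to the reference is
uninformative at 0.5.  With an empty reference the prior is flat (log 0.5 per
pair), which keeps stochastic search well-defined without norms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import networkx as nx

__all__ = [
    "EdgePrior",
    "build_reference_from_pairs",
    "edge_log_prior",
    "network_log_prior",
]


def build_reference_from_pairs(pairs: Iterable[tuple[str, str]]) -> nx.Graph:
    """Adjoin each cue–response pair with an edge; self-pairs are ignored.

    Duplicate and reversed pairs collapse to a single undirected edge.  An
    empty input yields an empty reference (every pair is then "unknown").
    """
    g = nx.Graph()
    for u, v in pairs:
        if u == v:
            continue
        g.add_edge(u, v)
    return g


@dataclass(frozen=True)
class EdgePrior:
    """Independent binomial edge prior relative to a reference network."""

    reference: nx.Graph = field(default_factory=nx.Graph)
    p_edge_in_ref: float = 2.0 / 3.0
    p_edge_not_in_ref: float = 0.4
    p_edge_unknown: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_edge_in_ref", "p_edge_not_in_ref", "p_edge_unknown"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {p}")

    def edge_prob(self, i: str, j: str) -> float:
        """Prior probability that the edge {i, j} is present."""
        if i == j:
            raise ValueError("self-pairs have no prior probability")
        ref = self.reference
        if i in ref and j in ref:
            return self.p_edge_in_ref if ref.has_edge(i, j) else self.p_edge_not_in_ref
        return self.p_edge_unknown


def edge_log_prior(i: str, j: str, prior: EdgePrior) -> float:
    """log P(G_ij = 1) under the edge-wise prior."""
    return math.log(prior.edge_prob(i, j))


def network_log_prior(net: nx.Graph, prior: EdgePrior) -> float:
    """log P(G) = sum over unordered node pairs of log P(G_ij = g_ij).

    Evaluated over the pairs of ``net``'s own node set (the participant's M
    observed responses), using the complement probability for absent edges.
    """
    total = 0.0
    for i, j in combinations(sorted(net.nodes()), 2):
        p = prior.edge_prob(i, j)
        total += math.log(p) if net.has_edge(i, j) else math.log1p(-p)
    return total
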