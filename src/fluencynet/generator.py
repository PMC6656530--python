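"""Generative simulator: noisy censored random walks and synthetic cohorts.

This module is the forward model matching :mod:`fluencynet.likelihood` and is
the package's main test oracle.  It also synthesizes two-group cohorts whose
contrast mirrors the clinical design this package targets: an impaired group
whose semantic networks carry extra spurious associations, whose monitoring
failure rate ``p_emit`` is higher, and who produce fewer and shorter fluency
lists than controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .corpus import FluencyCorpus, FluencyList

__all__ = [
    "WalkSimulator",
    "random_walk",
    "censor_walk",
    "simulate_list",
    "BaseNetworkSpec",
    "GroupSpec",
    "CohortSpec",
    "ParticipantTruth",
    "SyntheticCohort",
    "simulate_cohort",
]


class WalkSimulator:
    """Reusable sampler of noisy censored walks on a fixed network.

    Precomputes neighbour tables once so that large Monte-Carlo runs (10^5+
    lists) stay cheap.
    """

    def __init__(self, net: nx.Graph):
        self.nodes: tuple[str, ...] = tuple(sorted(net.nodes()))
        self._index = {v: i for i, v in enumerate(self.nodes)}
        self._nbrs: list[list[int]] = [
            sorted(self._index[u] for u in net.neighbors(v)) for v in self.nodes
        ]
        deg = np.array([len(nb) for nb in self._nbrs], dtype=float)
        self._deg = deg
        total = deg.sum()
        self._stationary = deg / total if total > 0 else deg
        self._net = net

    def _start(self, start: str | None, rng: np.random.Generator) -> int:
        if start is None:
            if self._stationary.sum() == 0:
                raise ValueError("network has no edges; stationary start undefined")
            return int(rng.choice(len(self.nodes), p=self._stationary))
        if start not in self._index:
            raise ValueError(f"start node {start!r} is not in the network")
        idx = self._index[start]
        if not self._nbrs[idx]:
            raise ValueError(f"start node {start!r} is isolated; the walk is undefined")
        return idx

    def walk(self, n_steps: int, rng: np.random.Generator, start: str | None = None) -> list[str]:
        """Uncensored walk of ``n_steps`` moves (returned sequence has n_steps+1 nodes)."""
        cur = self._start(start, rng)
        nbrs = self._nbrs
        out = [cur]
        for _ in range(n_steps):
            nb = nbrs[cur]
            cur = nb[int(rng.integers(len(nb)))]
            out.append(cur)
        return [self.nodes[i] for i in out]

    def sample_emissions(
        self,
        p_emit: float,
        n_emissions: int,
        rng: np.random.Generator,
        start: str | None = None,
        max_steps: int = 1_000_000,
    ) -> list[str]:
        """Walk from a stationary (or given) start until exactly ``n_emissions`` items."""
        if not 0.0 <= p_emit <= 1.0:
            raise ValueError(f"p_emit must lie in [0, 1], got {p_emit!r}")
        if n_emissions < 1:
            raise ValueError("n_emissions must be >= 1")
        cur = self._start(start, rng)
        if p_emit == 0.0:
            comp = nx.node_connected_component(self._net, self.nodes[cur])
            if n_emissions > len(comp):
                raise ValueError(
                    f"cannot emit {n_emissions} distinct items: only {len(comp)} "
                    "nodes are reachable and deterministic censoring forbids repeats"
                )
        nbrs = self._nbrs
        emitted = [cur]
        seen = {cur}
        steps = 0
        while len(emitted) < n_emissions:
            nb = nbrs[cur]
            if not nb:
                raise ValueError(f"walk reached isolated node {self.nodes[cur]!r}")
            cur = nb[int(rng.integers(len(nb)))]
            if cur not in seen:
                seen.add(cur)
                emitted.append(cur)
            elif p_emit > 0.0 and rng.random() < p_emit:
                emitted.append(cur)
            steps += 1
            if steps > max_steps:
                raise ValueError(
                    f"emission target {n_emissions} not reached within {max_steps} steps"
                )
        return [self.nodes[i] for i in emitted]


def random_walk(
    net: nx.Graph,
    n_steps: int,
    rng: np.random.Generator,
    start: str | None = None,
) -> list[str]:
    """Uniform-neighbour random walk; ``start=None`` draws from the stationary law."""
    return WalkSimulator(net).walk(n_steps, rng, start=start)


def censor_walk(walk: Sequence[str], p_emit: float, rng: np.random.Generator) -> list[str]:
    """Apply noisy censoring: first visits always emit, revisits emit w.p. ``p_emit``."""
    if not 0.0 <= p_emit <= 1.0:
        raise ValueError(f"p_emit must lie in [0, 1], got {p_emit!r}")
    seen: set[str] = set()
    out: list[str] = []
    for node in walk:
        if node not in seen:
            seen.add(node)
            out.append(node)
        elif p_emit > 0.0 and rng.random() < p_emit:
            out.append(node)
    return out


def simulate_list(
    net: nx.Graph,
    p_emit: float,
    n_emissions: int,
    rng: np.random.Generator,
    participant_id: str = "sim",
    list_id: str = "l1",
    start: str | None = None,
) -> FluencyList:
    """Sample one fluency list with exactly ``n_emissions`` emitted items."""
    items = WalkSimulator(net).sample_emissions(p_emit, n_emissions, rng, start=start)
    return FluencyList(participant_id, list_id, tuple(items))


# --------------------------------------------------------------------------
# Synthetic cohorts


@dataclass(frozen=True)
class BaseNetworkSpec:
    """Shared ground-truth semantic network for a synthetic cohort.

    The default is a connected Watts–Strogatz ring (small-world, like human
    semantic networks are reported to be), sized for desk-scale estimation.
    """

    kind: str = "watts_strogatz"
    n: int = 60
    k: int = 4
    p_rewire: float = 0.1
    p_edge: float = 0.3  # used by kind="erdos_renyi"

    def build(self, seed: int) -> nx.Graph:
        if self.kind == "watts_strogatz":
            g = nx.connected_watts_strogatz_graph(self.n, self.k, self.p_rewire, seed=seed)
        elif self.kind == "erdos_renyi":
            g = nx.erdos_renyi_graph(self.n, self.p_edge, seed=seed)
        else:
            raise ValueError(f"unknown base network kind {self.kind!r}")
        return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes()})


@dataclass(frozen=True)
class GroupSpec:
    """Generating conditions for one diagnostic group."""

    name: str
    n_participants: int
    spurious_edges: int
    p_emit: float | tuple[float, float]
    n_lists: int
    n_emissions: int | tuple[int, int]
    education: tuple[float, float] = (16.0, 2.5)  # mean, sd of years

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_lists < 1:
            raise ValueError("participant and list counts must be positive")
        lo, hi = (self.p_emit, self.p_emit) if np.isscalar(self.p_emit) else self.p_emit
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("p_emit values must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort of noisy censored walkers on a shared base network.

    Defaults are a desk-scale analogue of a fluency study contrasting
    controls (many long lists, rare perseverations, intact network) with an
    impaired group (fewer, shorter lists, frequent perseverations, and
    spurious random associations added to the network).
    """

    base: BaseNetworkSpec = field(default_factory=BaseNetworkSpec)
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("NC", 10, 0, 0.07, 8, 12, education=(16.0, 2.5)),
        GroupSpec("PAD", 10, 30, 0.35, 5, 8, education=(13.5, 2.5)),
    )
    seed: int = 0

    @staticmethod
    def from_dict(cfg: Mapping) -> "CohortSpec":
        base = BaseNetworkSpec(**cfg.get("base", {}))
        groups = tuple(
            GroupSpec(
                name=g["name"],
                n_participants=int(g["n_participants"]),
                spurious_edges=int(g.get("spurious_edges", 0)),
                p_emit=_maybe_pair(g["p_emit"], float),
                n_lists=int(g["n_lists"]),
                n_emissions=_maybe_pair(g["n_emissions"], int),
                education=tuple(g.get("education", (16.0, 2.5))),  # type: ignore[arg-type]
            )
            for g in cfg["groups"]
        ) if "groups" in cfg else CohortSpec().groups
        return CohortSpec(base=base, groups=groups, seed=int(cfg.get("seed", 0)))


def _maybe_pair(value, cast):
    if isinstance(value, (list, tuple)):
        lo, hi = value
        return (cast(lo), cast(hi))
    return cast(value)


@dataclass(frozen=True)
class ParticipantTruth:
    """Ground truth for one synthetic participant."""

    participant_id: str
    group: str
    network: nx.Graph
    p_emit: float
    education: float


@dataclass(frozen=True)
class SyntheticCohort:
    spec: CohortSpec
    base_network: nx.Graph
    corpora: tuple[FluencyCorpus, ...]
    truth: Mapping[str, ParticipantTruth]


def _add_spurious_edges(base: nx.Graph, k: int, rng: np.random.Generator) -> nx.Graph:
    """Turn ``k`` uniformly random non-edges of ``base`` into edges."""
    g = base.copy()
    non_edges = sorted(tuple(sorted(e)) for e in nx.non_edges(base))
    if k > len(non_edges):
        raise ValueError(f"requested {k} spurious edges but only {len(non_edges)} non-edges exist")
    if k:
        chosen = rng.choice(len(non_edges), size=k, replace=False)
        g.add_edges_from(non_edges[i] for i in chosen)
    return g


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> SyntheticCohort:
    """Generate corpora plus a full truth record for a two-group cohort.

    Deterministic under a fixed master seed; every participant gets an
    independent child stream derived from (seed, group index, participant
    index), so corpora do not change when other groups are resized.
    """
    master = spec.seed if seed is None else int(seed)
    base = spec.base.build(seed=int(np.random.default_rng([master, 991]).integers(2**31 - 1)))
    corpora: list[FluencyCorpus] = []
    truth: dict[str, ParticipantTruth] = {}
    for gi, group in enumerate(spec.groups):
        for pi in range(group.n_participants):
            rng = np.random.default_rng([master, gi, pi])
            pid = f"{group.name}{pi + 1:02d}"
            net = _add_spurious_edges(base, group.spurious_edges, rng)
            if np.isscalar(group.p_emit):
                p_emit = float(group.p_emit)  # type: ignore[arg-type]
            else:
                lo, hi = group.p_emit  # type: ignore[misc]
                p_emit = float(rng.uniform(lo, hi))
            edu = float(np.round(max(rng.normal(*group.education), 6.0), 1))
            sim = WalkSimulator(net)
            lists = []
            for li in range(group.n_lists):
                if np.isscalar(group.n_emissions):
                    n_em = int(group.n_emissions)  # type: ignore[arg-type]
                else:
                    lo_e, hi_e = group.n_emissions  # type: ignore[misc]
                    n_em = int(rng.integers(lo_e, hi_e + 1))
                items = sim.sample_emissions(p_emit, n_em, rng)
                lists.append(FluencyList(pid, f"v{li + 1:02d}", tuple(items)))
            corpora.append(FluencyCorpus(pid, tuple(lists)))
            truth[pid] = ParticipantTruth(pid, group.name, net, p_emit, edu)
    return SyntheticCohort(replace(spec, seed=master), base, tuple(corpora), truth)
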