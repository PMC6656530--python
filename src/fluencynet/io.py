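"""Readers and writers for fluency corpora, networks and configuration.

Fluency corpora travel as delimited text with a ``participant_id, list_id,
position, item`` header (comma or tab, auto-detected from the header line).
Networks travel as two-column edge lists (TSV) or GraphML; GraphML preserves
isolated nodes, the edge-list format does not.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import networkx as nx
import yaml

from .corpus import FluencyCorpus, FluencyList, normalize_label
from .errors import FormatError

__all__ = [
    "read_fluency_file",
    "write_fluency_file",
    "read_network",
    "write_network",
    "load_config",
]

_REQUIRED = ("participant_id", "list_id", "position", "item")


def _sniff_delimiter(header_line: str) -> str:
    if "\t" in header_line:
        return "\t"
    return ","


def read_fluency_file(path: str | Path) -> list[FluencyCorpus]:
    """Read a fluency corpus file into one :class:`FluencyCorpus` per participant.

    Items are normalized (lower-cased, whitespace-trimmed); rows within each
    list are ordered by ``position``, which must form a contiguous run.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        cols = [c.strip() for c in (reader.fieldnames or [])]
        missing = [c for c in _REQUIRED if c not in cols]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        # (participant, list) -> {position: item}, keyed in first-appearance order
        data: dict[str, dict[str, dict[int, str]]] = {}
        for rownum, row in enumerate(reader, start=2):
            pid = str(row["participant_id"]).strip()
            lid = str(row["list_id"]).strip()
            try:
                pos = int(str(row["position"]).strip())
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{rownum}: bad position {row['position']!r}") from exc
            item = normalize_label(row["item"] or "")
            if not item:
                raise FormatError(f"{path}:{rownum}: empty item label")
            lists = data.setdefault(pid, {})
            positions = lists.setdefault(lid, {})
            if pos in positions:
                raise FormatError(
                    f"{path}:{rownum}: duplicate position {pos} for participant "
                    f"{pid!r} list {lid!r}"
                )
            positions[pos] = item
    corpora = []
    for pid, lists in data.items():
        fls = []
        for lid, positions in lists.items():
            order = sorted(positions)
            if order != list(range(order[0], order[0] + len(order))):
                raise FormatError(
                    f"{path}: positions of participant {pid!r} list {lid!r} are "
                    f"not contiguous: {order}"
                )
            fls.append(FluencyList(pid, lid, tuple(positions[p] for p in order)))
        corpora.append(FluencyCorpus(pid, tuple(fls)))
    return corpora


def write_fluency_file(
    corpora: Iterable[FluencyCorpus], path: str | Path, delimiter: str = ","
) -> None:
    """Write corpora in the format :func:`read_fluency_file` reads back."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_REQUIRED)
        for corpus in corpora:
            for fl in corpus.lists:
                for pos, item in enumerate(fl.items, start=1):
                    writer.writerow([corpus.participant_id, fl.list_id, pos, item])


def _as_simple_graph(edges: Iterable[tuple[str, str]], where: str) -> nx.Graph:
    g = nx.Graph()
    for u, v in edges:
        u, v = normalize_label(u), normalize_label(v)
        if u == v:
            raise FormatError(f"{where}: self-loop on {u!r} is not a valid edge")
        g.add_edge(u, v)
    return g


def read_network(path: str | Path) -> nx.Graph:
    """Read an undirected, unweighted network from edge-list TSV or GraphML.

    Duplicate and reversed edge rows collapse to one edge; self-loops are
    rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        raw = nx.read_graphml(path)
        g = _as_simple_graph(((str(u), str(v)) for u, v in raw.edges()), str(path))
        for n in raw.nodes():
            g.add_node(normalize_label(str(n)))
        return g
    edges = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two labels, got {parts!r}")
            edges.append((parts[0], parts[1]))
    return _as_simple_graph(edges, str(path))


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Write a network as GraphML (``.graphml``) or two-column edge-list TSV."""
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        nx.write_graphml(net, path)
        return
    with path.open("w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{v}\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON key-value configuration file."""
    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return cfg


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column cue–response file (for building a prior reference)."""
    path = Path(path)
    pairs = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two labels, got {parts!r}")
            pairs.append((parts[0].strip(), parts[1].strip()))
    return pairs
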