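"""Domain containers for semantic fluency data.

A *fluency list* is the ordered sequence of responses one participant gave
during a single administration of the semantic fluency task ("name as many
animals as you can in one minute").  Repeats within a list — perseverations —
are kept verbatim: the retrieval model consumes them.  A *corpus* groups all
lists belonging to one participant (one per visit, typically); the corpus
vocabulary, of size M, is the node set of the semantic network estimated for
that participant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["FluencyList", "FluencyCorpus", "normalize_label"]

_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Lower-case, trim, and collapse internal whitespace.

    Deterministic and idempotent; no stemming or synonym mapping is applied
    (transcripts are assumed pre-cleaned).
    """
    return _WS.sub(" ", str(label).strip()).lower()


@dataclass(frozen=True)
class FluencyList:
    """One ordered response sequence from one participant visit."""

    participant_id: str
    list_id: str
    items: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError("a fluency list must contain at least one item")
        if any(not str(it).strip() for it in self.items):
            raise ValueError("fluency list items must be non-empty labels")
        object.__setattr__(self, "items", tuple(str(it) for it in self.items))

    def __len__(self) -> int:
        return len(self.items)

    @property
    def unique_items(self) -> tuple[str, ...]:
        """Unique items in first-occurrence order (the node order of A^l)."""
        return tuple(dict.fromkeys(self.items))

    @property
    def n_perseverations(self) -> int:
        """Responses identical to an earlier response in the same list."""
        return len(self.items) - len(self.unique_items)


@dataclass(frozen=True)
class FluencyCorpus:
    """All fluency lists of one participant (under one diagnosis)."""

    participant_id: str
    lists: tuple[FluencyList, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "lists", tuple(self.lists))
        if len(self.lists) < 1:
            raise ValueError("a corpus must contain at least one list")

    def __len__(self) -> int:
        return len(self.lists)

    @property
    def vocabulary(self) -> frozenset[str]:
        """Set of unique labels across all lists (the M network nodes)."""
        return frozenset(it for fl in self.lists for it in fl.items)

    @property
    def n_nodes(self) -> int:
        return len(self.vocabulary)

    def sorted_vocabulary(self) -> list[str]:
        return sorted(self.vocabulary)
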