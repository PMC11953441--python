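"""Score tables and rankings shared by every influence index.

A :class:`ScoreTable` maps each node of a contact graph to one real-valued
influence score under a named index (RWInf, a baseline centrality, or the
SIR mean spread).  Ranking uses competition ("1224") ranking: tied scores
share the smallest rank in their block, and rank 1 is the most influential
node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Mapping, Tuple

import math

Node = Hashable

__all__ = ["Node", "ScoreTable", "RankedList", "rank_nodes", "top_k"]


@dataclass(frozen=True)
class ScoreTable:
    """Mapping node -> influence score for one index."""

    index_name: str
    scores: Dict[Node, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, s in self.scores.items():
            if not math.isfinite(s):
                raise ValueError(f"non-finite score for node {node!r}: {s}")

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, node: Node) -> float:
        return self.scores[node]

    def __iter__(self):
        return iter(self.scores)

    def aligned_values(self, order) -> List[float]:
        """Scores listed in the given node order (for rank correlation)."""
        return [self.scores[n] for n in order]


@dataclass(frozen=True)
class RankedList:
    """Nodes sorted by descending score with competition ranks.

    Entries are ``(node, score, rank)``; ties share the smallest rank of
    their block and are ordered by node identifier for determinism.
    """

    index_name: str
    entries: Tuple[Tuple[Node, float, int], ...]

    def __len__(self) -> int:
        return len(self.entries)

    def nodes(self) -> List[Node]:
        return [node for node, _, _ in self.entries]

    def rank_of(self, node: Node) -> int:
        for n, _, r in self.entries:
            if n == node:
                return r
        raise KeyError(node)


def rank_nodes(table: ScoreTable) -> RankedList:
    """Rank nodes by descending score (rank 1 = most influential).

    Ties receive equal competition rank and deterministic identifier order.
    """
    if not table.scores:
        raise ValueError("cannot rank an empty score table")
    ordered = sorted(table.scores.items(), key=lambda kv: (-kv[1], str(kv[0])))
    entries = []
    rank = 0
    prev_score: float | None = None
    for pos, (node, score) in enumerate(ordered, start=1):
        if prev_score is None or score != prev_score:
            rank = pos
            prev_score = score
        entries.append((node, score, rank))
    return RankedList(index_name=table.index_name, entries=tuple(entries))


def top_k(table: ScoreTable, k: int) -> List[Node]:
    """The ``k`` most influential nodes, best first."""
    if not 1 <= k <= len(table.scores):
        raise ValueError(f"k={k} out of range for {len(table.scores)} nodes")
    return rank_nodes(table).nodes()[:k]


def scores_from_mapping(name: str, mapping: Mapping[Node, float]) -> ScoreTable:
    return ScoreTable(index_name=name, scores=dict(mapping))
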