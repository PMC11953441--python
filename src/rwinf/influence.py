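"""The RWInf influence score and its constituents.

RWInf ranks candidate superspreaders in a weighted contact graph whose edge
weights are contact durations.  It combines

* ``nwI(v)`` — neighborhood weighted influence, the sum of incident edge
  weights (single-level, local);
* ``smlI(v) = sum_{u != v} nwI(u) / cd(v, u)`` — single-and-multiple-level
  influence, where the contact distance ``cd`` is the shortest-path hop
  count, so influence decays with network "level" (global);
* ``ld(v) = (triangles(v) + 1) * degree(v)`` — local density, a
  clustering-aware local size;

into ``RWInf(v) = ld(v) * smlI(v)``.  Higher score = more influential;
rank 1 is the top spreader.

Contact distances default to unweighted hop counts (every denominator in
the score is an integer level count); ``distance="weighted-inverse"``
instead runs Dijkstra on edge lengths ``1/W`` for sensitivity analysis.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping

import networkx as nx

from .scoring import Node, RankedList, ScoreTable, rank_nodes

__all__ = [
    "UNREACHABLE",
    "neighborhood_weighted_influence",
    "contact_distances",
    "smli_from_parts",
    "smli_scores",
    "triangle_count",
    "local_density",
    "rwinf_scores",
    "rank_nodes",
]

#: Sentinel distance for a node unreachable from the source.
UNREACHABLE = math.inf


def neighborhood_weighted_influence(G: nx.Graph) -> ScoreTable:
    """nwI(v) = sum of v's incident edge weights; 0 for an isolated node."""
    scores = {v: float(sum(d["weight"] for _, _, d in G.edges(v, data=True)))
              for v in G.nodes}
    return ScoreTable(index_name="nwI", scores=scores)


def contact_distances(
    G: nx.Graph, source: Node, distance: str = "hop"
) -> Dict[Node, float]:
    """Contact distances from ``source`` to every node.

    ``"hop"`` (default) counts edges on the shortest path — the number of
    contact "levels" separating two individuals.  ``"weighted-inverse"``
    uses Dijkstra on lengths ``1/W`` so strong ties are short.  Unreachable
    nodes carry :data:`UNREACHABLE`.
    """
    if source not in G:
        raise KeyError(f"source {source!r} not in graph")
    if distance == "hop":
        reach = nx.single_source_shortest_path_length(G, source)
    elif distance == "weighted-inverse":
        H = _inverse_length_view(G)
        reach = nx.single_source_dijkstra_path_length(H, source, weight="length")
    else:
        raise ValueError(f"unknown distance mode {distance!r}")
    return {v: float(reach.get(v, UNREACHABLE)) for v in G.nodes}


def _inverse_length_view(G: nx.Graph) -> nx.Graph:
    H = nx.Graph()
    H.add_nodes_from(G.nodes)
    for u, v, d in G.edges(data=True):
        w = d["weight"]
        if not w > 0:
            raise ValueError(f"edge {u!r}-{v!r} has nonpositive weight {w}")
        H.add_edge(u, v, length=1.0 / w)
    return H


def smli_from_parts(
    nwi: ScoreTable, distances_from_v: Mapping[Node, float], v: Node
) -> float:
    """smlI(v) from precomputed nwI values and a distance row.

    Sums ``nwI(u) / cd(v, u)`` over reachable ``u != v``; unreachable nodes
    contribute nothing (their distance is effectively infinite).
    """
    total = 0.0
    for u, d in distances_from_v.items():
        if u == v or not (0 < d < UNREACHABLE):
            continue
        total += nwi[u] / d
    return total


def smli_scores(G: nx.Graph, distance: str = "hop") -> ScoreTable:
    """smlI for every node of ``G``."""
    nwi = neighborhood_weighted_influence(G)
    scores = {
        v: smli_from_parts(nwi, contact_distances(G, v, distance=distance), v)
        for v in G.nodes
    }
    return ScoreTable(index_name="smlI", scores=scores)


def triangle_count(G: nx.Graph, v: Node) -> int:
    """Number of triangles through ``v`` on the unweighted skeleton."""
    if v not in G:
        raise KeyError(f"node {v!r} not in graph")
    return int(nx.triangles(G, v))


def local_density(G: nx.Graph, v: Node) -> float:
    """ld(v) = (triangles(v) + 1) * degree(v); 0 for an isolated node.

    The +1 keeps triangle-free nodes in play: a node with no closed
    neighborhood triads still spreads through its degree.
    """
    k = G.degree(v)
    if k == 0:
        return 0.0
    return float((triangle_count(G, v) + 1) * k)


def local_density_scores(G: nx.Graph) -> ScoreTable:
    tri = nx.triangles(G)
    scores = {
        v: 0.0 if G.degree(v) == 0 else float((tri[v] + 1) * G.degree(v))
        for v in G.nodes
    }
    return ScoreTable(index_name="ld", scores=scores)


def rwinf_scores(G: nx.Graph, distance: str = "hop") -> ScoreTable:
    """RWInf(v) = ld(v) * smlI(v) for every node."""
    ld = local_density_scores(G)
    sml = smli_scores(G, distance=distance)
    scores = {v: ld[v] * sml[v] for v in G.nodes}
    return ScoreTable(index_name="rwinf", scores=scores)
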