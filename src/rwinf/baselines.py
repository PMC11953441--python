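"""Eight comparison indices for weighted-network spreader ranking.

Five structural baselines derive edge weights from degree and k-shell
measures (W_k-shell applies its exponent formula to the real duration
weights; Wks, ksd^w, ngsc and HIC ignore durations by construction), and
three classical centralities (weighted degree, betweenness, closeness) use
the duration weights directly.  All operate on an undirected graph with a
positive ``weight`` attribute per edge.

Shortest-path centralities interpret durations as tie *strengths*: the
default edge length is ``1/W`` so strongly connected pairs are close.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import networkx as nx

from .scoring import Node, ScoreTable

__all__ = [
    "BaselineParams",
    "NodeFeatures",
    "kshell_decomposition",
    "node_features",
    "weighted_kshell",
    "wks_scores",
    "ksd_w_scores",
    "ngsc_scores",
    "h_index",
    "hic_scores",
    "weighted_degree",
    "weighted_betweenness",
    "weighted_closeness",
    "BASELINE_INDICES",
    "compute_index",
]


@dataclass(frozen=True)
class BaselineParams:
    """Tunable parameters of the structural baselines.

    ``alpha1``/``beta1`` weight degree vs strength in the W_k-shell degree
    (both 1 in the originating study); ``alpha1_wks`` mixes degree and
    neighbor-degree weight in Wks (0.5); ``alpha1_ksd``/``mu1`` and
    ``t1``/``t2`` mix degree and k-shell in ksd^w and ngsc (giant-component
    tuned in the source studies; 0.5 here).
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha1_wks: float = 0.5
    alpha1_ksd: float = 0.5
    mu1: float = 0.5
    t1: float = 0.5
    t2: float = 0.5
    distance_mode: str = "inverse_weight"


@dataclass(frozen=True)
class NodeFeatures:
    """Structural quantities of one node used by the baselines."""

    k: int
    ks: int
    H: int
    C: float
    tri: int
    I: float


def kshell_decomposition(G: nx.Graph) -> Dict[Node, Tuple[int, int, int]]:
    """Iterative minimum-degree pruning on the unweighted skeleton.

    Each pruning round removes every node whose current degree does not
    exceed the running shell threshold; the threshold is the minimum degree
    seen so far (it never decreases).  Returns, per node,
    ``(ks, removal_round, total_rounds)`` with 1-based rounds.

    The removal round refines ks: within one shell, peripheral nodes fall in
    earlier rounds than deeply embedded ones (used by the HIC iteration
    factor).
    """
    H = G.copy()
    result: Dict[Node, Tuple[int, int]] = {}
    shell = 0
    rounds = 0
    while H.number_of_nodes():
        degs = dict(H.degree())
        shell = max(shell, min(degs.values()))
        rounds += 1
        doomed = [v for v, d in degs.items() if d <= shell]
        for v in doomed:
            result[v] = (shell, rounds)
        H.remove_nodes_from(doomed)
    return {v: (ks, r, rounds) for v, (ks, r) in result.items()}


def _iteration_factor(ks: int, removal_round: int, total_rounds: int) -> float:
    """k-shell iteration factor I = ks * (1 + n/m).

    ``n`` is the pruning round at which the node was removed and ``m`` the
    total number of rounds, so nodes surviving longer within a shell score
    higher.  Isolated behind this function so an alternative definition is
    a one-line swap.
    """
    return ks * (1.0 + removal_round / total_rounds)


def node_features(G: nx.Graph) -> Dict[Node, NodeFeatures]:
    """Degree, k-shell, H-index, clustering, triangles and iteration factor."""
    shells = kshell_decomposition(G)
    tri = nx.triangles(G)
    clus = nx.clustering(G)
    feats = {}
    for v in G.nodes:
        ks, n_v, m = shells[v]
        feats[v] = NodeFeatures(
            k=G.degree(v),
            ks=ks,
            H=h_index(G, v),
            C=float(clus[v]),
            tri=int(tri[v]),
            I=_iteration_factor(ks, n_v, m),
        )
    return feats


def _strength(G: nx.Graph, v: Node) -> float:
    return float(sum(d["weight"] for _, _, d in G.edges(v, data=True)))


def weighted_kshell(
    G: nx.Graph,
    alpha1: float = 1.0,
    beta1: float = 1.0,
    rounding=round,
) -> ScoreTable:
    """W_k-shell: shell index from pruning on the weighted degree.

    Each node's weighted degree ``k' = [k^a1 * strength^b1]^(1/(a1+b1))`` is
    recomputed as the graph shrinks; ``k'`` is real-valued, so it is rounded
    to the nearest integer (``rounding`` configurable) before the standard
    minimum-first peeling.
    """
    if not (alpha1 > 0 and beta1 > 0):
        raise ValueError("alpha1 and beta1 must be positive")

    def kprime(H: nx.Graph, v: Node) -> int:
        k = H.degree(v)
        s = _strength(H, v)
        return int(rounding((k ** alpha1 * s ** beta1) ** (1.0 / (alpha1 + beta1))))

    H = G.copy()
    scores: Dict[Node, float] = {}
    shell = 0
    while H.number_of_nodes():
        vals = {v: kprime(H, v) for v in H.nodes}
        shell = max(shell, min(vals.values()))
        doomed = [v for v, d in vals.items() if d <= shell]
        for v in doomed:
            scores[v] = float(shell)
        H.remove_nodes_from(doomed)
    return ScoreTable(index_name="wkshell", scores=scores)


def wks_scores(G: nx.Graph, alpha1: float = 0.5) -> ScoreTable:
    """Wks: weighted degree with degree-sum edge weights.

    Edge weights are ``k_u + k_v`` (durations ignored by construction);
    ``k^W(v) = a1*k(v) + (1-a1) * sum_{u in N(v)} (k(v)+k(u))``.
    """
    deg = dict(G.degree())
    scores = {
        v: alpha1 * deg[v] + (1.0 - alpha1) * sum(deg[v] + deg[u] for u in G[v])
        for v in G.nodes
    }
    return ScoreTable(index_name="wks", scores={v: float(s) for v, s in scores.items()})


def ksd_w_scores(G: nx.Graph, alpha1: float = 0.5, mu1: float = 0.5) -> ScoreTable:
    """ksd^w: neighborhood sum of degree/k-shell product edge weights.

    ``W_uv = (a1*k_u + m1*ks_u) * (a1*k_v + m1*ks_v)``, summed over the
    1-hop neighborhood.
    """
    deg = dict(G.degree())
    shells = kshell_decomposition(G)
    mix = {v: alpha1 * deg[v] + mu1 * shells[v][0] for v in G.nodes}
    scores = {v: float(sum(mix[v] * mix[u] for u in G[v])) for v in G.nodes}
    return ScoreTable(index_name="ksdw", scores=scores)


def ngsc_scores(G: nx.Graph, t1: float = 0.5, t2: float = 0.5) -> ScoreTable:
    """ngsc: neighborhood sum of mixed k-shell/degree terms for both ends."""
    deg = dict(G.degree())
    shells = kshell_decomposition(G)
    mix = {v: t1 * shells[v][0] + t2 * deg[v] for v in G.nodes}
    scores = {v: float(sum(mix[v] + mix[u] for u in G[v])) for v in G.nodes}
    return ScoreTable(index_name="ngsc", scores=scores)


def h_index(G: nx.Graph, v: Node) -> int:
    """Largest h such that v has at least h neighbors of degree >= h."""
    if v not in G:
        raise KeyError(f"node {v!r} not in graph")
    degs = sorted((G.degree(u) for u in G[v]), reverse=True)
    h = 0
    for i, d in enumerate(degs, start=1):
        if d >= i:
            h = i
        else:
            break
    return h


def hic_scores(G: nx.Graph) -> ScoreTable:
    """HIC: neighborhood sum of H-index/iteration-factor/clustering weights.

    ``W_uv = H_u*I_u/(1+C_u) + H_v*I_v/(1+C_v)`` with I the k-shell
    iteration factor; HIC(v) sums W over v's incident edges.
    """
    feats = node_features(G)
    term = {v: feats[v].H * feats[v].I / (1.0 + feats[v].C) for v in G.nodes}
    scores = {v: float(sum(term[v] + term[u] for u in G[v])) for v in G.nodes}
    return ScoreTable(index_name="hic", scores=scores)


def weighted_degree(G: nx.Graph) -> ScoreTable:
    """C_D^W: total contact time with direct neighbors (node strength)."""
    scores = {v: _strength(G, v) for v in G.nodes}
    return ScoreTable(index_name="wdeg", scores=scores)


def _length_graph(G: nx.Graph, distance_mode: str) -> nx.Graph:
    H = nx.Graph()
    H.add_nodes_from(G.nodes)
    for u, v, d in G.edges(data=True):
        w = d["weight"]
        if not w > 0:
            raise ValueError(f"edge {u!r}-{v!r} has nonpositive weight {w}")
        if distance_mode == "inverse_weight":
            H.add_edge(u, v, length=1.0 / w)
        elif distance_mode == "raw_weight":
            H.add_edge(u, v, length=float(w))
        else:
            raise ValueError(f"unknown distance_mode {distance_mode!r}")
    return H


def weighted_betweenness(G: nx.Graph, distance_mode: str = "inverse_weight") -> ScoreTable:
    """C_B^W: fraction of weighted shortest paths through each node.

    Paths use edge lengths ``1/W`` by default (strong ties are short);
    endpoints are excluded and counts are unnormalized.
    """
    H = _length_graph(G, distance_mode)
    bc = nx.betweenness_centrality(H, weight="length", normalized=False)
    return ScoreTable(index_name="wbet", scores={v: float(s) for v, s in bc.items()})


def weighted_closeness(G: nx.Graph, distance_mode: str = "inverse_weight") -> ScoreTable:
    """C_C^W: reciprocal of summed weighted distances to reachable nodes.

    On a disconnected graph the sum runs over the node's component;
    isolated nodes score 0.
    """
    H = _length_graph(G, distance_mode)
    scores = {}
    for v in H.nodes:
        dist = nx.single_source_dijkstra_path_length(H, v, weight="length")
        total = sum(d for u, d in dist.items() if u != v)
        scores[v] = 1.0 / total if total > 0 else 0.0
    return ScoreTable(index_name="wclo", scores=scores)


BASELINE_INDICES = (
    "wkshell", "wks", "ksdw", "ngsc", "hic", "wdeg", "wbet", "wclo",
)


def compute_index(
    G: nx.Graph, name: str, params: BaselineParams | None = None
) -> ScoreTable:
    """Dispatch an index by name (the eight baselines plus ``rwinf``)."""
    from .influence import rwinf_scores

    p = params or BaselineParams()
    table = {
        "wkshell": lambda: weighted_kshell(G, p.alpha1, p.beta1),
        "wks": lambda: wks_scores(G, p.alpha1_wks),
        "ksdw": lambda: ksd_w_scores(G, p.alpha1_ksd, p.mu1),
        "ngsc": lambda: ngsc_scores(G, p.t1, p.t2),
        "hic": lambda: hic_scores(G),
        "wdeg": lambda: weighted_degree(G),
        "wbet": lambda: weighted_betweenness(G, p.distance_mode),
        "wclo": lambda: weighted_closeness(G, p.distance_mode),
        "rwinf": lambda: rwinf_scores(G),
    }
    if name not in table:
        raise ValueError(f"unknown index {name!r}; choose from {sorted(table)}")
    return table[name]()
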