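"""Discrete-time SIR simulation: the ground truth for spreader ranking.

A node's true spreading capability is estimated by seeding a synchronous
susceptible-infected-recovered process at that node and averaging the final
number of ever-infected (recovered) individuals over many independent runs.
At each step every infected node independently infects each susceptible
neighbor with probability ``beta``, then recovers with probability ``lam``
(default 1, so a node transmits for exactly one step).  A node infected at
step t starts transmitting at step t+1.

Transmission ignores edge weights by default — the SIR score is a
method-agnostic ground truth and the threshold heuristic
``beta_th ~ <k>/<k^2>`` is an unweighted-network result.  A ``weighted``
mode (per-contact probability ``1 - (1-beta)^(W/interval)``) is available
for sensitivity studies.

Reproducibility: each (source, run) pair draws from its own substream
derived from the root seed, so per-node scores do not depend on evaluation
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np

from .scoring import Node, ScoreTable

__all__ = [
    "SIRConfig",
    "SIRResult",
    "epidemic_threshold",
    "sir_run",
    "sir_influence",
    "sir_ground_truth",
]


@dataclass(frozen=True)
class SIRConfig:
    """Parameters of the SIR ground-truth estimate.

    ``beta``: per-contact infection probability per step, in [0, 1].
    ``lam``: recovery probability per step (1 = one-step infectiousness).
    ``runs``: independent repetitions averaged per seed node.
    ``seed``: root RNG seed; all substreams derive from it.
    ``weighted``: use duration-dependent transmission probabilities.
    ``interval``: seconds per contact tick in weighted mode.
    """

    beta: float = 0.1
    lam: float = 1.0
    runs: int = 1000
    seed: int = 0
    weighted: bool = False
    interval: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0,1], got {self.beta}")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError(f"lam must be in (0,1], got {self.lam}")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass(frozen=True)
class SIRResult:
    """Mean final epidemic size when seeding at one node."""

    node: Node
    mean_spread: float
    per_run: Optional[np.ndarray] = field(default=None, repr=False, compare=False)


def epidemic_threshold(G: nx.Graph) -> float:
    """Epidemic threshold estimate ``<k> / <k^2>`` on the unweighted skeleton.

    Infection probabilities above this value sustain spreading in the
    heterogeneous mean-field approximation.
    """
    if G.number_of_edges() == 0:
        raise ValueError("graph has no edges; threshold undefined")
    degs = np.array([d for _, d in G.degree()], dtype=float)
    return float(degs.mean() / (degs ** 2).mean())


def _adjacency(G: nx.Graph):
    """Index nodes deterministically and build neighbor/probability lists."""
    nodes = sorted(G.nodes, key=str)
    idx = {v: i for i, v in enumerate(nodes)}
    nbrs: List[np.ndarray] = []
    wts: List[np.ndarray] = []
    for v in nodes:
        adj = sorted(G[v], key=str)
        nbrs.append(np.array([idx[u] for u in adj], dtype=np.int64))
        wts.append(np.array([G[v][u].get("weight", 1.0) for u in adj], dtype=float))
    return nodes, idx, nbrs, wts


def _edge_probs(wts: Sequence[np.ndarray], beta: float, weighted: bool,
                interval: float) -> List[np.ndarray]:
    if not weighted:
        return [np.full(len(w), beta) for w in wts]
    return [1.0 - (1.0 - beta) ** (w / interval) for w in wts]


def _single_run(nbrs, probs, n: int, source_i: int, lam: float,
                rng: np.random.Generator) -> int:
    state = np.zeros(n, dtype=np.int8)  # 0=S, 1=I, 2=R
    state[source_i] = 1
    infected = [source_i]
    while infected:
        newly: List[int] = []
        for i in infected:
            targets = nbrs[i]
            if len(targets):
                hits = rng.random(len(targets)) < probs[i]
                for j in targets[hits]:
                    if state[j] == 0:
                        state[j] = 1
                        newly.append(int(j))
        if lam >= 1.0:
            for i in infected:
                state[i] = 2
            infected = newly
        else:
            recovered = rng.random(len(infected)) < lam
            still = [i for i, r in zip(infected, recovered) if not r]
            for i, r in zip(infected, recovered):
                if r:
                    state[i] = 2
            infected = still + newly
    return int(np.count_nonzero(state == 2))


def sir_run(G: nx.Graph, source: Node, config: SIRConfig,
            rng: Optional[np.random.Generator] = None) -> int:
    """One SIR realization seeded at ``source``; returns the final recovered count."""
    if source not in G:
        raise KeyError(f"source {source!r} not in graph")
    nodes, idx, nbrs, wts = _adjacency(G)
    probs = _edge_probs(wts, config.beta, config.weighted, config.interval)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _single_run(nbrs, probs, len(nodes), idx[source], config.lam, rng)


def sir_influence(G: nx.Graph, source: Node, config: SIRConfig,
                  keep_runs: bool = False) -> SIRResult:
    """Mean spread over ``config.runs`` independent realizations from ``source``.

    The substream for each source derives from ``(seed, source index)``, so
    the result is identical whether computed alone or as part of
    :func:`sir_ground_truth`.
    """
    if source not in G:
        raise KeyError(f"source {source!r} not in graph")
    nodes, idx, nbrs, wts = _adjacency(G)
    probs = _edge_probs(wts, config.beta, config.weighted, config.interval)
    counts = _runs_for_source(nbrs, probs, len(nodes), idx[source],
                              config, idx[source])
    return SIRResult(node=source, mean_spread=float(counts.mean()),
                     per_run=counts if keep_runs else None)


def _runs_for_source(nbrs, probs, n: int, source_i: int, config: SIRConfig,
                     stream_key: int) -> np.ndarray:
    rng = np.random.default_rng([config.seed, stream_key])
    counts = np.empty(config.runs, dtype=np.int64)
    for r in range(config.runs):
        counts[r] = _single_run(nbrs, probs, n, source_i, config.lam, rng)
    return counts


def sir_ground_truth(G: nx.Graph, config: SIRConfig) -> ScoreTable:
    """Mean SIR spread per seed node, assembled into a ScoreTable named 'sir'."""
    nodes, idx, nbrs, wts = _adjacency(G)
    probs = _edge_probs(wts, config.beta, config.weighted, config.interval)
    scores: Dict[Node, float] = {}
    for v in nodes:
        counts = _runs_for_source(nbrs, probs, len(nodes), idx[v], config, idx[v])
        scores[v] = float(counts.mean())
    return ScoreTable(index_name="sir", scores=scores)
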