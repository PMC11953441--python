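"""Evaluating influence indices against SIR ground truth.

The evaluation protocol ranks nodes by an index and by their mean SIR
spread, and measures agreement with Kendall's tau-b (tie-corrected) at each
infection probability on a grid above the epidemic threshold:
``beta_i = beta_th + 0.01 * i`` for ``i = 1..iter``.  The grid average
``sigma(tau)`` summarizes an index across the epidemic regime.  Two
complementary metrics: monotonicity ``M(I)`` penalizes tied ranks
(1 = all ranks unique, 0 = all tied), and the improvement percentage
``eta`` compares a reference index's tau against a comparator's, sign-aware.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import stats

from .baselines import BaselineParams, compute_index
from .scoring import Node, ScoreTable, rank_nodes, top_k
from .sir import SIRConfig, epidemic_threshold, sir_ground_truth

__all__ = [
    "EvalReport",
    "GraphSummary",
    "kendall_tau",
    "beta_grid",
    "average_tau",
    "monotonicity",
    "improvement_pct",
    "top_k",
    "graph_summary",
    "evaluate_all",
]


@dataclass(frozen=True)
class GraphSummary:
    """Structural summary of a contact network (largest component if disconnected)."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    diameter: int
    mean_shortest_path: float
    mean_clustering: float
    beta_th: float
    connected: bool


@dataclass
class EvalReport:
    """Per-beta taus, grid-average sigma(tau), monotonicity and improvements."""

    beta_grid: Tuple[float, ...]
    per_beta_tau: Dict[Tuple[str, float], float] = field(default_factory=dict)
    sigma_tau: Dict[str, float] = field(default_factory=dict)
    monotonicity: Dict[str, float] = field(default_factory=dict)
    improvement: Dict[Tuple[str, str, float], float] = field(default_factory=dict)
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "beta_grid": list(self.beta_grid),
            "seed": self.seed,
            "per_beta_tau": [
                {"index": i, "beta": b, "tau": t}
                for (i, b), t in sorted(self.per_beta_tau.items())
            ],
            "sigma_tau": dict(sorted(self.sigma_tau.items())),
            "monotonicity": dict(sorted(self.monotonicity.items())),
            "improvement": [
                {"reference": r, "comparator": c, "beta": b, "eta_pct": e}
                for (r, c, b), e in sorted(self.improvement.items())
            ],
        }


def kendall_tau(x: ScoreTable, y: ScoreTable) -> float:
    """Tie-adjusted Kendall's tau-b between two score tables.

    Both tables must cover exactly the same node set; scores are aligned by
    node before correlating, so the result is invariant to node order.
    """
    if set(x.scores) != set(y.scores):
        raise ValueError("score tables cover different node sets")
    order = sorted(x.scores, key=str)
    xv = x.aligned_values(order)
    yv = y.aligned_values(order)
    tau = stats.kendalltau(xv, yv, variant="b").statistic
    if math.isnan(tau):  # one vector fully tied: no rank information
        return 0.0
    return float(tau)


def beta_grid(G: nx.Graph, iterations: int = 15, step: float = 0.01,
              mode: str = "threshold") -> List[float]:
    """Infection-probability grid for the tau sweep.

    ``"threshold"`` (default): ``beta_th + step*i`` for ``i = 1..iterations``,
    clamping out values above 1 with a warning.  ``"absolute"``:
    ``step, 2*step, ..., iterations*step`` regardless of the threshold.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if mode == "threshold":
        b0 = epidemic_threshold(G)
        grid = [b0 + step * i for i in range(1, iterations + 1)]
    elif mode == "absolute":
        grid = [step * i for i in range(1, iterations + 1)]
    else:
        raise ValueError(f"unknown beta grid mode {mode!r}")
    kept = [b for b in grid if b <= 1.0]
    if len(kept) < len(grid):
        warnings.warn(
            f"dropped {len(grid) - len(kept)} beta values above 1", stacklevel=2
        )
    return kept


def average_tau(
    G: nx.Graph,
    index_fn: Callable[[nx.Graph], ScoreTable],
    sir_config_base: SIRConfig,
    iterations: int = 15,
    grid_mode: str = "threshold",
) -> Tuple[float, Dict[float, float]]:
    """sigma(tau) for one index: the mean tau over the beta grid.

    Returns ``(sigma_tau, {beta: tau})``.  The index is computed once; the
    SIR ground truth is re-simulated at every beta with the same root seed.
    """
    grid = beta_grid(G, iterations=iterations, mode=grid_mode)
    scores = index_fn(G)
    taus: Dict[float, float] = {}
    for b in grid:
        cfg = SIRConfig(beta=b, lam=sir_config_base.lam, runs=sir_config_base.runs,
                        seed=sir_config_base.seed, weighted=sir_config_base.weighted,
                        interval=sir_config_base.interval)
        taus[b] = kendall_tau(scores, sir_ground_truth(G, cfg))
    return sum(taus.values()) / len(taus), taus


def monotonicity(scores: ScoreTable) -> float:
    """Ranking uniqueness M(I) = [1 - sum V_i(V_i - 1) / (V(V-1))]^2.

    ``V_i`` are the sizes of tied-score groups.  1 when all scores are
    distinct; 0 when all are equal.  Undefined for fewer than 2 nodes.
    """
    n = len(scores)
    if n < 2:
        raise ValueError("monotonicity needs at least 2 nodes")
    groups: Dict[float, int] = {}
    for s in scores.scores.values():
        groups[s] = groups.get(s, 0) + 1
    tied = sum(c * (c - 1) for c in groups.values())
    return (1.0 - tied / (n * (n - 1))) ** 2


def improvement_pct(tau_ref: float, tau_cmp: float) -> float:
    """Improvement eta (%) of the reference index over a comparator.

    ``(tau_ref - tau_cmp)/tau_cmp * 100`` when the comparator's tau is
    positive, ``(tau_ref - tau_cmp)/(-tau_cmp) * 100`` when negative, and 0
    when it is exactly 0.  Positive eta means the reference ranks closer to
    the SIR ground truth.
    """
    for t in (tau_ref, tau_cmp):
        if not -1.0 <= t <= 1.0:
            raise ValueError(f"tau {t} outside [-1, 1]")
    if tau_cmp > 0:
        return (tau_ref - tau_cmp) / tau_cmp * 100.0
    if tau_cmp < 0:
        return (tau_ref - tau_cmp) / (-tau_cmp) * 100.0
    return 0.0


def graph_summary(G: nx.Graph) -> GraphSummary:
    """Mean degree, diameter, mean path length, clustering and beta_th.

    Path statistics are computed on the largest connected component; the
    ``connected`` flag records whether that was the whole graph.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    connected = nx.is_connected(G)
    H = G if connected else G.subgraph(max(nx.connected_components(G), key=len))
    if not connected:
        warnings.warn("graph disconnected; path statistics use largest component",
                      stacklevel=2)
    degs = [d for _, d in G.degree()]
    return GraphSummary(
        n_nodes=G.number_of_nodes(),
        n_edges=G.number_of_edges(),
        mean_degree=float(np.mean(degs)),
        diameter=int(nx.diameter(H)),
        mean_shortest_path=float(nx.average_shortest_path_length(H)),
        mean_clustering=float(nx.average_clustering(G)),
        beta_th=epidemic_threshold(G),
        connected=connected,
    )


def evaluate_all(
    G: nx.Graph,
    indices: Sequence[str],
    sir_config: SIRConfig,
    iterations: int = 15,
    grid_mode: str = "threshold",
    reference: str = "rwinf",
    params: BaselineParams | None = None,
) -> EvalReport:
    """Full evaluation: per-beta taus, sigma(tau), M(I) and improvements.

    Simulates the SIR ground truth once per beta and correlates every index
    against it; improvement percentages are reported for the ``reference``
    index (when present) against every other index at each beta.
    """
    grid = beta_grid(G, iterations=iterations, mode=grid_mode)
    tables = {name: compute_index(G, name, params) for name in indices}
    report = EvalReport(beta_grid=tuple(grid), seed=sir_config.seed)
    for name, table in tables.items():
        report.monotonicity[name] = monotonicity(table)
    for b in grid:
        cfg = SIRConfig(beta=b, lam=sir_config.lam, runs=sir_config.runs,
                        seed=sir_config.seed, weighted=sir_config.weighted,
                        interval=sir_config.interval)
        sir_scores = sir_ground_truth(G, cfg)
        for name, table in tables.items():
            report.per_beta_tau[(name, b)] = kendall_tau(table, sir_scores)
    for name in tables:
        taus = [report.per_beta_tau[(name, b)] for b in grid]
        report.sigma_tau[name] = sum(taus) / len(taus)
    if reference in tables:
        for name in tables:
            if name == reference:
                continue
            for b in grid:
                report.improvement[(reference, name, b)] = improvement_pct(
                    report.per_beta_tau[(reference, b)],
                    report.per_beta_tau[(name, b)],
                )
    return report
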