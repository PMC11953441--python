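"""Synthetic contact streams and weighted graphs with known ground truth.

The stream generator emulates the structure of badge-based proximity data:
pairs of individuals meet in sessions whose start times follow a Poisson
process, session lengths are geometric in 20-second ticks, and each active
session emits one contact record per tick.  The generator records every
session it creates, so the session-merging and edge-weighting pipeline can
be tested for *exact* recovery, not approximate agreement: session starts
are snapped to the tick grid and consecutive sessions of a pair are kept at
least two ticks apart, which makes sessionization with the default gap
tolerance uniquely invertible.

It makes no attempt to replicate empirical degree or duration distributions
of real deployments — it exists so the pipeline is testable without data
downloads.

Also embedded here: the worked toy-network fixture (26 nodes A-Z) with its
published neighborhood-influence values and contact distances, used to pin
the score computation to known constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import networkx as nx
import numpy as np

from .temporal import ContactEvent, Session

__all__ = [
    "StreamSpec",
    "StreamGroundTruth",
    "generate_contact_stream",
    "generate_weighted_graph",
    "WorkedExampleFixture",
    "worked_example_fixture",
]


@dataclass(frozen=True)
class StreamSpec:
    """Parameters of a synthetic contact stream.

    ``contact_rate`` is the expected number of new sessions per pair per
    hour; ``mean_session_ticks`` the mean of the geometric session-length
    distribution in units of ``interval``.
    """

    n_individuals: int = 20
    t_horizon: int = 8 * 3600
    contact_rate: float = 0.2
    mean_session_ticks: float = 3.0
    interval: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.contact_rate < 0 or self.mean_session_ticks < 1:
            raise ValueError("contact_rate must be >= 0 and mean_session_ticks >= 1")
        if self.interval <= 0 or self.t_horizon < self.interval:
            raise ValueError("interval must be positive and horizon >= interval")


@dataclass
class StreamGroundTruth:
    """Every session the generator created, plus per-pair total durations."""

    sessions: List[Session] = field(default_factory=list)
    pair_durations: Dict[Tuple[str, str], int] = field(default_factory=dict)

    @property
    def total_duration(self) -> int:
        return sum(self.pair_durations.values())


def _node_names(n: int) -> List[str]:
    width = len(str(n - 1))
    return [f"p{str(i).zfill(width)}" for i in range(n)]


def generate_contact_stream(
    spec: StreamSpec,
) -> Tuple[List[ContactEvent], StreamGroundTruth]:
    """Draw a contact stream and its exact session-level ground truth.

    For each pair the number of sessions is Poisson with mean
    ``contact_rate * horizon_hours``; starts are uniform on the tick grid
    and lengths geometric with the configured mean.  Sessions of one pair
    are kept disjoint with at least a 2-tick gap (overflowing or colliding
    draws are dropped), so the emitted records are exactly invertible by
    sessionization with ``max_gap = interval``.

    Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    names = _node_names(spec.n_individuals)
    ticks_total = spec.t_horizon // spec.interval
    horizon_hours = spec.t_horizon / 3600.0
    p_geom = 1.0 / spec.mean_session_ticks
    events: List[ContactEvent] = []
    truth = StreamGroundTruth()
    for i in range(spec.n_individuals):
        for j in range(i + 1, spec.n_individuals):
            pair = (names[i], names[j])
            n_sessions = rng.poisson(spec.contact_rate * horizon_hours)
            if n_sessions == 0:
                continue
            starts = np.sort(rng.integers(1, ticks_total + 1, size=n_sessions))
            lengths = rng.geometric(p_geom, size=n_sessions)
            kept: List[Tuple[int, int]] = []
            last_end = -10**9
            for s, ln in zip(starts, lengths):
                end = s + int(ln) - 1
                if s >= last_end + 2 and end <= ticks_total:
                    kept.append((int(s), end))
                    last_end = end
            if not kept:
                continue
            dur = 0
            for s, end in kept:
                st = (s - 1) * spec.interval
                et = end * spec.interval
                truth.sessions.append(Session(pair=pair, st=st, et=et))
                dur += et - st
                for tick in range(s, end + 1):
                    events.append(
                        ContactEvent(t=tick * spec.interval, u=pair[0], v=pair[1])
                    )
            truth.pair_durations[pair] = dur
    events.sort()
    truth.sessions.sort(key=lambda s: (s.pair, s.st))
    return events, truth


_WEIGHT_DISTS = ("lognormal", "uniform", "unit")


def generate_weighted_graph(
    model: str,
    n: int,
    model_param: float = 0.1,
    weight_dist: str = "lognormal",
    seed: int = 0,
) -> nx.Graph:
    """Random weighted graph: topology from a named model, heavy-tailed weights.

    Models: ``erdos_renyi`` (``model_param`` = edge probability),
    ``barabasi_albert`` (edges per new node), ``ring``.  The default
    lognormal(mu=4, sigma=1) weight distribution mimics heavy-tailed
    contact-duration data; ``uniform`` draws on (0, 1]; ``unit`` sets all
    weights to 1.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    if model == "erdos_renyi":
        G = nx.gnp_random_graph(n, model_param, seed=int(rng.integers(2**31)))
    elif model == "barabasi_albert":
        m = max(1, int(model_param))
        G = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    elif model == "ring":
        G = nx.cycle_graph(n)
    else:
        raise ValueError(f"unknown graph model {model!r}")
    if weight_dist not in _WEIGHT_DISTS:
        raise ValueError(f"unknown weight_dist {weight_dist!r}")
    names = _node_names(n)
    G = nx.relabel_nodes(G, dict(zip(range(n), names)))
    for u, v in G.edges():
        if weight_dist == "lognormal":
            w = float(rng.lognormal(mean=4.0, sigma=1.0))
        elif weight_dist == "uniform":
            w = float(1.0 - rng.random())  # (0, 1]
        else:
            w = 1.0
        G[u][v]["weight"] = w
    return G


@dataclass(frozen=True)
class WorkedExampleFixture:
    """The published toy-network constants for node A of the 26-node example.

    ``nwi_map`` holds the neighborhood weighted influence of every node;
    ``dist_from_a`` the contact distances (hop counts) from A to the other
    25 nodes.  Expected values carry the source's 3-decimal rounding, hence
    the stated tolerances.
    """

    nwi_map: Dict[str, float]
    dist_from_a: Dict[str, int]
    k_a: int
    tri_a: int
    expected_smli_a: float  # +/- 0.001
    expected_ld_a: float    # exact
    expected_rwinf_a: float  # +/- 0.05


def worked_example_fixture() -> WorkedExampleFixture:
    """The toy-network fixture with its published expected scores."""
    nwi = {
        "A": 16, "B": 20, "C": 20, "D": 35, "E": 9, "F": 11, "G": 1, "H": 2,
        "I": 17, "J": 5, "K": 18, "L": 7, "M": 3, "N": 15, "O": 5, "P": 5,
        "Q": 5, "R": 8, "S": 4, "T": 13, "U": 6, "V": 2, "W": 13, "X": 1,
        "Y": 2, "Z": 7,
    }
    dist = {}
    for node in "BCDEF":
        dist[node] = 1
    for node in "GHIKNQRVW":
        dist[node] = 2
    for node in "JLMOPSTXYZ":
        dist[node] = 3
    dist["U"] = 4
    return WorkedExampleFixture(
        nwi_map={k: float(v) for k, v in nwi.items()},
        dist_from_a=dist,
        k_a=5,
        tri_a=5,
        expected_smli_a=154.333,
        expected_ld_a=30.0,
        expected_rwinf_a=4629.99,
    )
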