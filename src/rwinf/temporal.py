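"""Contact-duration edge weights from timestamped proximity streams.

SocioPatterns-style deployments record a line ``t i j`` whenever badges
``i`` and ``j`` were in face-to-face range during the 20-second sampling
window ending at ``t``.  Consecutive records for a pair are merged into
*sessions*; the total session duration (seconds) of a pair is its edge
weight in the static weighted contact graph — the "connection strength"
used by every duration-aware influence index in this package.

Conventions
-----------
* A session over records at ``t_1 < ... < t_n`` (max gap ``g``) starts at
  ``t_1 - interval`` and ends at ``t_n``, so an isolated record contributes
  one full sampling interval rather than zero.  Set ``isolated_zero=True``
  in :func:`sessionize` for the alternative ``st = t_1`` convention.
* Node identifiers are opaque strings — never coerced to integers, so badge
  IDs with leading zeros survive a round trip.
* Timestamps must be integers (seconds); anything else is rejected.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Sequence, TextIO, Tuple, Union

import networkx as nx

__all__ = [
    "ContactEvent",
    "Session",
    "ParseError",
    "parse_contact_events",
    "sessionize",
    "pair_weight",
    "build_weighted_graph",
    "load_weighted_edgelist",
    "write_weighted_edgelist",
    "write_session_table",
    "ordinal_weight",
    "ordinalize_graph",
]

DEFAULT_INTERVAL = 20  # SocioPatterns sampling interval, seconds

# Ordinal contact-duration levels (seconds): <5 min, 5-15 min, 15 min-1 h, >1 h.
ORDINAL_BOUNDS = (300, 900, 3600)


class ParseError(ValueError):
    """A malformed line in a contact stream or edge list."""


@dataclass(frozen=True, order=True)
class ContactEvent:
    """One proximity record: pair {u, v} in contact at second ``t``.

    The pair is stored in canonical (sorted) order so ``(u, v, t)`` and
    ``(v, u, t)`` compare equal.
    """

    t: int
    u: str
    v: str

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError(f"self-contact {self.u!r} at t={self.t}")
        if self.t < 0:
            raise ValueError(f"negative timestamp {self.t}")
        if self.u > self.v:  # canonicalize unordered pair
            a, b = self.v, self.u
            object.__setattr__(self, "u", a)
            object.__setattr__(self, "v", b)

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.u, self.v)


@dataclass(frozen=True)
class Session:
    """One maximal contact interval of a pair: ``(st, et]`` in seconds."""

    pair: Tuple[str, str]
    st: int
    et: int

    def __post_init__(self) -> None:
        if self.et <= self.st:
            raise ValueError(f"session end {self.et} not after start {self.st}")

    @property
    def duration(self) -> int:
        return self.et - self.st


def _open_text(stream: Union[str, TextIO, Iterable[str]], dialect: str):
    if hasattr(stream, "read") or not isinstance(stream, str):
        return stream
    if dialect.endswith("_gz") or stream.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(stream, "rb"), encoding="utf-8")
    return open(stream, "r", encoding="utf-8")


def parse_contact_events(
    stream: Union[str, TextIO, Iterable[str]],
    dialect: str = "tij",
) -> List[ContactEvent]:
    """Parse a contact stream into time-sorted, de-duplicated events.

    Parameters
    ----------
    stream
        A path, an open text handle, or any iterable of lines.  Paths ending
        in ``.gz`` (or dialects suffixed ``_gz``) are opened as gzip text.
    dialect
        ``"tij"`` reads columns ``t i j`` (the SocioPatterns layout);
        ``"ijt"`` reads ``i j t``.  No auto-detection: column order must be
        stated explicitly.

    Returns
    -------
    list of ContactEvent, nondecreasing in time, duplicates for the same
    (pair, t) collapsed.  An empty stream yields an empty list.

    Raises
    ------
    ParseError
        On a line with fewer than 3 fields, a non-integer timestamp, or a
        self-contact, naming the 1-based line number.
    """
    base = dialect[:-3] if dialect.endswith("_gz") else dialect
    if base not in ("tij", "ijt"):
        raise ValueError(f"unknown dialect {dialect!r}")
    fh = _open_text(stream, dialect)
    events = set()
    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected >=3 fields, got {len(fields)}")
        if base == "tij":
            t_str, u, v = fields[0], fields[1], fields[2]
        else:
            u, v, t_str = fields[0], fields[1], fields[2]
        try:
            t = int(t_str)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer timestamp {t_str!r}") from None
        try:
            events.add(ContactEvent(t=t, u=u, v=v))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return sorted(events)


def sessionize(
    timestamps: Sequence[int],
    interval: int = DEFAULT_INTERVAL,
    max_gap: int | None = None,
    pair: Tuple[str, str] = ("", ""),
    isolated_zero: bool = False,
) -> List[Session]:
    """Merge one pair's sorted contact timestamps into sessions.

    Consecutive records at most ``max_gap`` seconds apart belong to one
    session.  A session over ``t_1 < ... < t_n`` has ``st = t_1 - interval``
    and ``et = t_n`` (duration ``t_n - t_1 + interval``), so a single
    isolated record lasts one sampling interval.  With ``isolated_zero``
    the start is ``t_1`` and singleton sessions are dropped.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if max_gap is None:
        max_gap = interval
    if max_gap < interval:
        raise ValueError("max_gap must be >= interval")
    ts = list(timestamps)
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("timestamps must be strictly increasing")
    if not ts:
        return []
    offset = 0 if isolated_zero else interval
    sessions: List[Session] = []
    start = ts[0]
    last = ts[0]
    for t in ts[1:]:
        if t - last > max_gap:
            if last - (start - offset) > 0:
                sessions.append(Session(pair=pair, st=start - offset, et=last))
            start = t
        last = t
    if last - (start - offset) > 0:
        sessions.append(Session(pair=pair, st=start - offset, et=last))
    return sessions


def pair_weight(sessions: Sequence[Session]) -> int:
    """Total contact duration (seconds) over a pair's sessions."""
    return sum(s.duration for s in sessions)


def build_weighted_graph(
    events: Iterable[ContactEvent],
    interval: int = DEFAULT_INTERVAL,
    max_gap: int | None = None,
    isolated_zero: bool = False,
) -> nx.Graph:
    """Static weighted contact graph from a parsed event stream.

    One undirected edge per pair that ever co-occurs; the ``weight``
    attribute is the pair's total contact duration in seconds.  Pairs whose
    sessions all collapse to zero duration (possible only with
    ``isolated_zero``) are omitted, as are their otherwise-isolated nodes.
    """
    per_pair: Dict[Tuple[str, str], List[int]] = {}
    for ev in events:
        per_pair.setdefault(ev.pair, []).append(ev.t)
    G = nx.Graph()
    for pair, ts in per_pair.items():
        ts = sorted(set(ts))
        w = pair_weight(
            sessionize(ts, interval=interval, max_gap=max_gap, pair=pair,
                       isolated_zero=isolated_zero)
        )
        if w > 0:
            G.add_edge(pair[0], pair[1], weight=float(w))
    return G


def iter_pair_sessions(
    events: Iterable[ContactEvent],
    interval: int = DEFAULT_INTERVAL,
    max_gap: int | None = None,
    isolated_zero: bool = False,
) -> Iterator[Session]:
    """All sessions of all pairs, ordered by pair then time."""
    per_pair: Dict[Tuple[str, str], List[int]] = {}
    for ev in events:
        per_pair.setdefault(ev.pair, []).append(ev.t)
    for pair in sorted(per_pair):
        ts = sorted(set(per_pair[pair]))
        yield from sessionize(ts, interval=interval, max_gap=max_gap, pair=pair,
                              isolated_zero=isolated_zero)


def load_weighted_edgelist(stream: Union[str, TextIO, Iterable[str]]) -> nx.Graph:
    """Read a pre-weighted undirected edge list ``u v weight``.

    Weights must be numeric and positive; a duplicate pair is an error
    because its aggregation would be ambiguous.
    """
    fh = _open_text(stream, "edgelist")
    G = nx.Graph()
    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise ParseError(f"line {lineno}: expected 3 fields, got {len(fields)}")
        u, v, w_str = fields
        try:
            w = float(w_str)
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric weight {w_str!r}") from None
        if not w > 0:
            raise ParseError(f"line {lineno}: nonpositive weight {w}")
        if u == v:
            raise ParseError(f"line {lineno}: self-loop on {u!r}")
        if G.has_edge(u, v):
            raise ParseError(f"line {lineno}: duplicate edge {u!r}-{v!r}")
        G.add_edge(u, v, weight=w)
    return G


def write_weighted_edgelist(G: nx.Graph, fh: TextIO, header: str | None = None) -> None:
    """Write ``u<TAB>v<TAB>weight`` lines, pairs in canonical sorted order."""
    if header:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
    for u, v in sorted(tuple(sorted((str(a), str(b)))) for a, b in G.edges()):
        w = G[u][v]["weight"]
        fh.write(f"{u}\t{v}\t{w!r}\n")


def write_session_table(sessions: Iterable[Session], fh: TextIO) -> None:
    fh.write("u\tv\tst\tet\tduration\n")
    for s in sessions:
        fh.write(f"{s.pair[0]}\t{s.pair[1]}\t{s.st}\t{s.et}\t{s.duration}\n")


def ordinal_weight(duration: float) -> int:
    """Map a contact duration (seconds) to the 4-level ordinal weight.

    Level 1: under 5 minutes; 2: 5-15 min; 3: 15 min-1 h; 4: 1 h or more.
    Boundaries are left-closed on the upper category (exactly 300 s -> 2).
    """
    if duration < 0:
        raise ValueError(f"negative duration {duration}")
    level = 1
    for bound in ORDINAL_BOUNDS:
        if duration >= bound:
            level += 1
    return level


def ordinalize_graph(G: nx.Graph) -> nx.Graph:
    """Copy of ``G`` with each duration weight replaced by its ordinal level."""
    H = G.copy()
    for u, v, data in H.edges(data=True):
        data["weight"] = float(ordinal_weight(data["weight"]))
    return H
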