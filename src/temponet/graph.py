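"""Temporal contact-network data model and contact-list I/O.

A temporal network is a node set together with a stream of undirected
contact events ``(u, v, t)`` on integer snapshot indices: the edge (u, v)
is active during snapshot ``t``.  This is the natural container for
SocioPatterns-style face-to-face proximity data, where one snapshot
corresponds to a fixed recording interval (nominally 20 s).

The event indicator is binary: at most one event is stored per
``(u, v, t)`` triple, and duplicate input records collapse to one event.
Node identifiers are opaque strings ordered lexicographically; that total
order canonicalizes node pairs and breaks every tie downstream.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

__all__ = [
    "ContactEvent",
    "TemporalNetwork",
    "StaticAggregate",
    "read_contact_list",
    "write_contact_list",
    "temporal_degree",
    "temporal_neighbors",
    "snapshot",
    "aggregate",
]


class ContactListError(ValueError):
    """Raised for malformed contact-list input (message names the line)."""


def canonical_pair(u: str, v: str) -> tuple[str, str]:
    """Order an undirected node pair under the global (lexicographic) order."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True, order=True)
class ContactEvent:
    """One undirected contact at one snapshot.

    Stored in canonical order (``u < v``) so that undirected equality is
    plain tuple equality.  Self-contacts are rejected.
    """

    u: str
    v: str
    t: int

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError(f"self-contact {self.u!r} at t={self.t} is not allowed")
        if self.u > self.v:
            u, v = self.u, self.v
            object.__setattr__(self, "u", v)
            object.__setattr__(self, "v", u)
        if self.t < 0:
            raise ValueError(f"negative snapshot index t={self.t}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.u, self.v)


class TemporalNetwork:
    """A set of nodes plus a deduplicated stream of contact events.

    Parameters
    ----------
    events:
        Iterable of ``ContactEvent`` or raw ``(u, v, t)`` triples.
    nodes:
        Optional extra node identifiers (isolated nodes are legal and are
        preserved by snapshots and aggregation).
    t_start, t_end:
        Observation window.  Defaults to the span of the events
        (``[0, 0]`` for an event-free network).
    """

    def __init__(
        self,
        events: Iterable[ContactEvent | tuple] = (),
        nodes: Iterable[str] = (),
        t_start: int | None = None,
        t_end: int | None = None,
    ) -> None:
        evset: set[ContactEvent] = set()
        for e in events:
            if not isinstance(e, ContactEvent):
                e = ContactEvent(*e)
            evset.add(e)
        self._events: tuple[ContactEvent, ...] = tuple(
            sorted(evset, key=lambda e: (e.t, e.u, e.v))
        )
        nodeset = set(nodes)
        for e in self._events:
            nodeset.add(e.u)
            nodeset.add(e.v)
        self._nodes: tuple[str, ...] = tuple(sorted(nodeset))
        lo = min((e.t for e in self._events), default=0)
        hi = max((e.t for e in self._events), default=0)
        self.t_start = lo if t_start is None else t_start
        self.t_end = hi if t_end is None else t_end
        if self.t_start > self.t_end:
            raise ValueError("t_start must not exceed t_end")
        for e in self._events:
            if not (self.t_start <= e.t <= self.t_end):
                raise ValueError(
                    f"event {e} outside the window [{self.t_start}, {self.t_end}]"
                )
        # per-edge sorted activation times, and events grouped per snapshot
        self._edge_times: dict[tuple[str, str], tuple[int, ...]] = {}
        self._by_time: dict[int, tuple[ContactEvent, ...]] = {}
        per_edge: dict[tuple[str, str], list[int]] = {}
        per_time: dict[int, list[ContactEvent]] = {}
        for e in self._events:
            per_edge.setdefault(e.pair, []).append(e.t)
            per_time.setdefault(e.t, []).append(e)
        self._edge_times = {p: tuple(ts) for p, ts in per_edge.items()}
        self._by_time = {t: tuple(es) for t, es in per_time.items()}

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        """All node identifiers in canonical order."""
        return self._nodes

    @property
    def events(self) -> tuple[ContactEvent, ...]:
        """All events sorted by (time, pair)."""
        return self._events

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_snapshots(self) -> int:
        """Number of snapshots in the observation window (inclusive)."""
        return self.t_end - self.t_start + 1

    def edge_times(self, u: str, v: str) -> tuple[int, ...]:
        """Sorted activation times of the undirected edge (u, v)."""
        return self._edge_times.get(canonical_pair(u, v), ())

    @property
    def edge_time_map(self) -> Mapping[tuple[str, str], tuple[int, ...]]:
        return self._edge_times

    def events_at(self, t: int) -> tuple[ContactEvent, ...]:
        return self._by_time.get(t, ())

    def has_node(self, i: str) -> bool:
        return i in set(self._nodes)

    def _require_node(self, i: str) -> None:
        if i not in self._node_set:
            raise KeyError(f"unknown node {i!r}")

    @property
    def _node_set(self) -> frozenset[str]:
        ns = getattr(self, "_node_set_cache", None)
        if ns is None:
            ns = frozenset(self._nodes)
            self._node_set_cache = ns
        return ns

    def __len__(self) -> int:
        return len(self._events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TemporalNetwork):
            return NotImplemented
        return (
            self._nodes == other._nodes
            and self._events == other._events
            and (self.t_start, self.t_end) == (other.t_start, other.t_end)
        )

    def __repr__(self) -> str:
        return (
            f"TemporalNetwork(n_nodes={self.n_nodes}, n_events={len(self._events)}, "
            f"window=[{self.t_start}, {self.t_end}])"
        )

    def remove_nodes(self, drop: Iterable[str]) -> "TemporalNetwork":
        """Copy of the network with the given nodes and all their events removed."""
        dropset = set(drop)
        return TemporalNetwork(
            (e for e in self._events if e.u not in dropset and e.v not in dropset),
            nodes=(n for n in self._nodes if n not in dropset),
            t_start=self.t_start,
            t_end=self.t_end,
        )


@dataclass
class StaticAggregate:
    """Union of all snapshots: weighted static graph w(i,j) = contact count."""

    nodes: tuple[str, ...]
    edge_weights: dict[tuple[str, str], int] = field(default_factory=dict)

    def neighbors(self, i: str) -> set[str]:
        out = set()
        for (u, v) in self.edge_weights:
            if u == i:
                out.add(v)
            elif v == i:
                out.add(u)
        return out

    def degree(self, i: str) -> int:
        """Static degree D(i): number of distinct aggregate neighbours."""
        return sum(1 for (u, v) in self.edge_weights if i in (u, v))

    def weight(self, u: str, v: str) -> int:
        return self.edge_weights.get(canonical_pair(u, v), 0)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), w in self.edge_weights.items():
            g.add_edge(u, v, weight=w)
        return g


# -- I/O -----------------------------------------------------------------

def _open_text(source) -> IO[str]:
    if hasattr(source, "read"):
        return source
    path = str(source)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def read_contact_list(source, time_unit: int = 1) -> TemporalNetwork:
    """Parse a SocioPatterns-style contact list (``t i j`` per line).

    Raw timestamps are rebinned to consecutive snapshot indices
    ``(t - t_min) // time_unit``; extra columns after the first three are
    ignored, lines starting with ``#`` are comments, duplicate triples
    collapse to one event, and non-monotone timestamps are accepted.

    Raises
    ------
    ContactListError
        For malformed lines (with line number) or self-contacts.
    """
    if time_unit < 1:
        raise ValueError("time_unit must be a positive integer")
    fh = _open_text(source)
    raw: list[tuple[int, str, str]] = []
    for lineno, line in enumerate(fh, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) < 3:
            raise ContactListError(
                f"line {lineno}: expected at least 3 fields 't i j', got {len(parts)}"
            )
        try:
            t = int(parts[0])
        except ValueError as exc:
            raise ContactListError(
                f"line {lineno}: non-integer timestamp {parts[0]!r}"
            ) from exc
        i, j = parts[1], parts[2]
        if i == j:
            raise ContactListError(f"line {lineno}: self-contact on node {i!r}")
        raw.append((t, i, j))
    if not raw:
        return TemporalNetwork()
    t_min = min(t for t, _, _ in raw)
    events = {ContactEvent(i, j, (t - t_min) // time_unit) for t, i, j in raw}
    return TemporalNetwork(events)


def write_contact_list(net: TemporalNetwork, target) -> None:
    """Write events as ``t i j`` lines (snapshot indices, canonical pairs)."""
    own = not hasattr(target, "write")
    fh = open(str(target), "w", encoding="utf-8") if own else target
    try:
        for e in net.events:
            fh.write(f"{e.t} {e.u} {e.v}\n")
    finally:
        if own:
            fh.close()


# -- windowed views ------------------------------------------------------

def temporal_neighbors(net: TemporalNetwork, i: str, ts: int | None = None,
                       te: int | None = None) -> set[str]:
    """Nodes in contact with *i* at any snapshot of the inclusive window."""
    net._require_node(i)
    ts = net.t_start if ts is None else ts
    te = net.t_end if te is None else te
    out: set[str] = set()
    for (u, v), times in net.edge_time_map.items():
        if i not in (u, v):
            continue
        if any(ts <= t <= te for t in times):
            out.add(v if u == i else u)
    return out


def temporal_degree(net: TemporalNetwork, i: str, ts: int | None = None,
                    te: int | None = None, mode: str = "distinct_neighbors") -> int:
    """Temporal degree of node *i* over the inclusive window ``[ts, te]``.

    ``distinct_neighbors`` (default) counts nodes contacted at least once in
    the window; ``contact_count`` counts every (neighbour, snapshot) contact.
    The two readings coincide on single-snapshot windows.
    """
    net._require_node(i)
    ts = net.t_start if ts is None else ts
    te = net.t_end if te is None else te
    if ts > te:
        raise ValueError(f"window start {ts} exceeds end {te}")
    if mode == "distinct_neighbors":
        return len(temporal_neighbors(net, i, ts, te))
    if mode == "contact_count":
        total = 0
        for (u, v), times in net.edge_time_map.items():
            if i in (u, v):
                total += sum(1 for t in times if ts <= t <= te)
        return total
    raise ValueError(f"unknown degree mode {mode!r}")


def snapshot(net: TemporalNetwork, t: int) -> StaticAggregate:
    """The static graph of contacts active at snapshot *t* (all weights 1)."""
    if not (net.t_start <= t <= net.t_end):
        raise ValueError(f"snapshot {t} outside window [{net.t_start}, {net.t_end}]")
    weights = {e.pair: 1 for e in net.events_at(t)}
    return StaticAggregate(nodes=net.nodes, edge_weights=weights)


def aggregate(net: TemporalNetwork) -> StaticAggregate:
    """Union of all snapshots with w(i,j) = number of active snapshots."""
    weights = {pair: len(times) for pair, times in net.edge_time_map.items()}
    return StaticAggregate(nodes=net.nodes, edge_weights=weights)
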