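"""Temporal spanning trees, base cycles and the temporal cycle matrix.

Base cycles are built the classical way — one non-tree (chord) edge plus
the tree path between its endpoints — on top of an *earliest-arrival*
spanning tree rooted at a chosen node.  A chord is temporally admissible
when it has an activation no earlier than both of its endpoints' arrival
times in the tree, so every base cycle can actually be closed by a flow
that left the root.  A cycle's formation time is the latest event among
its constituents (the tree events on the path and the chord event), which
makes the per-time-step cycle sets well defined: the cycles present at
time t are exactly those completed by t.

Unlike time-respecting paths, the cycle flow may chain within a single
snapshot: a flow reaching a node at time t spreads through the whole
contact subgraph of snapshot t.  This weak (>=) time ordering is what
makes a network whose events all share one snapshot behave exactly like
its static aggregate — its base-cycle count equals the aggregate
cyclomatic number E - N + C — while networks with spread-out activations
retain genuinely temporal cycle sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import ContactEvent, TemporalNetwork, aggregate, canonical_pair

__all__ = [
    "BaseCycle",
    "CycleMatrix",
    "temporal_spanning_tree",
    "enumerate_base_cycles",
    "cycles_at_time",
    "cycle_matrix",
    "edge_cycle_count",
]


@dataclass(frozen=True)
class BaseCycle:
    """A base cycle: closed node sequence (closure implied), its chord event
    and the time at which the last of its constituent events occurred."""

    node_sequence: tuple[str, ...]
    chord: ContactEvent
    formation_time: int

    def __post_init__(self) -> None:
        if len(set(self.node_sequence)) < 3:
            raise ValueError("a cycle needs at least 3 distinct nodes")

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.node_sequence)

    def edges(self) -> list[tuple[str, str]]:
        """Consecutive (cyclic) node pairs, canonically ordered."""
        seq = self.node_sequence
        return [canonical_pair(seq[k], seq[(k + 1) % len(seq)]) for k in range(len(seq))]

    def __len__(self) -> int:
        return len(self.node_sequence)


def _canonical_cycle(seq: list[str]) -> tuple[str, ...]:
    """Rotate/reflect a cyclic sequence to start at the smallest node, with
    the lexicographically smaller neighbour second."""
    n = len(seq)
    start = seq.index(min(seq))
    fwd = [seq[(start + k) % n] for k in range(n)]
    rev = [seq[(start - k) % n] for k in range(n)]
    return tuple(fwd) if fwd[1:] <= rev[1:] else tuple(rev)


def _tree(net: TemporalNetwork, root: str, t0: int | None = None):
    """Earliest-arrival flow tree: arrival times and the parent event per node.

    Within a snapshot the flow chains through the snapshot's contact
    subgraph (weak time ordering); across snapshots arrivals are earliest.
    Tie-breaks follow the canonical edge order, so the tree is
    deterministic.
    """
    net._require_node(root)
    t0 = net.t_start if t0 is None else t0
    arrival: dict[str, int] = {root: t0}
    parent_event: dict[str, ContactEvent] = {}
    for t in sorted(set(e.t for e in net.events)):
        if t < t0:
            continue
        # breadth-first closure within the snapshot, in canonical edge order
        changed = True
        while changed:
            changed = False
            newly: dict[str, ContactEvent] = {}
            for e in sorted(net.events_at(t), key=lambda e: (e.u, e.v)):
                for a, b in ((e.u, e.v), (e.v, e.u)):
                    if a in arrival and t >= arrival[a] and b not in arrival \
                            and b not in newly:
                        newly[b] = e
            for b in sorted(newly):
                arrival[b] = t
                parent_event[b] = newly[b]
                changed = True
    return arrival, parent_event


def temporal_spanning_tree(net: TemporalNetwork, root: str) -> set[ContactEvent]:
    """Events of the earliest-arrival tree from *root* (one per reached node)."""
    _, parent_event = _tree(net, root)
    return set(parent_event.values())


def enumerate_base_cycles(net: TemporalNetwork, root: str | None = None
                          ) -> list[BaseCycle]:
    """All temporally admissible base cycles over the earliest-arrival tree.

    One candidate cycle per aggregate edge outside the tree; a candidate is
    kept when the chord has an activation no earlier than both endpoint
    arrival times.  Chords are visited in canonical edge order, so the
    output is bit-reproducible.  With ``root=None`` every aggregate
    component is enumerated from its smallest node; with an explicit root
    only that root's reachable part is covered.
    """
    if root is None:
        if not net.nodes:
            return []
        import networkx as nx

        g = aggregate(net).to_networkx()
        cycles: list[BaseCycle] = []
        for comp in sorted(nx.connected_components(g), key=min):
            cycles.extend(enumerate_base_cycles(net, root=min(comp)))
        return cycles
    arrival, parent_event = _tree(net, root)
    tree_pairs = {e.pair for e in parent_event.values()}
    parent = {b: e.u if e.v == b else e.v for b, e in parent_event.items()}

    def path_to_root(x: str) -> list[str]:
        out = [x]
        while out[-1] != root:
            out.append(parent[out[-1]])
        return out

    cycles: list[BaseCycle] = []
    for pair in sorted(net.edge_time_map):
        if pair in tree_pairs:
            continue
        u, v = pair
        if u not in arrival or v not in arrival:
            continue
        admissible = [t for t in net.edge_times(u, v)
                      if t >= max(arrival[u], arrival[v])]
        if not admissible:
            continue
        chord = ContactEvent(u, v, min(admissible))
        pu, pv = path_to_root(u), path_to_root(v)
        sv = set(pv)
        meet = next(x for x in pu if x in sv)
        seq = pu[: pu.index(meet) + 1] + list(reversed(pv[: pv.index(meet)]))
        tree_times = [
            parent_event[x].t
            for branch in (pu[: pu.index(meet)], pv[: pv.index(meet)])
            for x in branch
        ]
        cycles.append(
            BaseCycle(
                node_sequence=_canonical_cycle(seq),
                chord=chord,
                formation_time=max([chord.t] + tree_times),
            )
        )
    return cycles


def cycles_at_time(cycles: list[BaseCycle], t: int) -> list[BaseCycle]:
    """Cycles whose formation completed by snapshot *t*."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return [c for c in cycles if c.formation_time <= t]


@dataclass
class CycleMatrix:
    """Co-membership counts: AC[i, j] = number of cycles containing both
    nodes; the diagonal counts each node's cycles."""

    order: tuple[str, ...]
    AC: np.ndarray

    def index(self, node: str) -> int:
        return self.order.index(node)

    def count(self, i: str, j: str) -> int:
        return int(self.AC[self.index(i), self.index(j)])


def cycle_matrix(cycles: list[BaseCycle], nodes) -> CycleMatrix:
    order = tuple(sorted(nodes))
    idx = {n: k for k, n in enumerate(order)}
    ac = np.zeros((len(order), len(order)), dtype=int)
    for c in cycles:
        members = [idx[n] for n in c.node_set]
        for a in members:
            for b in members:
                ac[a, b] += 1
    return CycleMatrix(order=order, AC=ac)


def edge_cycle_count(cycles: list[BaseCycle], e: tuple[str, str]) -> int:
    """P(e): cycles containing *e* as a consecutive (cyclic) node pair."""
    pair = canonical_pair(*e)
    return sum(1 for c in cycles if pair in c.edges())


def edge_cycle_factor(cycles: list[BaseCycle], e: tuple[str, str]) -> int:
    """lambda(e) = P(e) + 1, the cycle factor used by semi-local integration."""
    return edge_cycle_count(cycles, e) + 1


def cyclomatic_number(net: TemporalNetwork) -> int:
    """E - N + C of the static aggregate (upper bound on base-cycle count)."""
    agg = aggregate(net)
    g = agg.to_networkx()
    import networkx as nx

    return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)
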