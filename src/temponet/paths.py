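"""Time-respecting paths, temporal distances and reachability.

A time-respecting path is a sequence of contact events with strictly
increasing snapshot times in which consecutive events share a node.  The
source may depart on any event at time >= t0; every relay hop must occur
strictly after the relaying node was reached (no multi-hop spreading
within one snapshot).

Temporal distance is measured as arrival time minus departure time, so a
direct contact at the departure snapshot has distance 0; unreachable
targets are at ``math.inf``.
"""

from __future__ import annotations

import math

from .graph import TemporalNetwork

__all__ = [
    "earliest_arrival",
    "temporal_distance",
    "count_shortest_temporal_paths",
    "reachable_set",
]

INF = math.inf


def _forward_sweep(net: TemporalNetwork, source: str, t0: int):
    """Single-source earliest-arrival sweep over events in time order.

    Returns (arrival, sigma, preds): earliest arrival time per node, the
    number of distinct earliest-arrival paths, and the predecessor sets of
    the shortest-path DAG (the relaying nodes of the optimal final hops).
    """
    net._require_node(source)
    arrival: dict[str, float] = {source: t0}
    sigma: dict[str, int] = {source: 1}
    preds: dict[str, set[str]] = {source: set()}
    times = sorted(t for t in set(e.t for e in net.events) if t >= t0)
    for t in times:
        contributions: dict[str, dict[str, int]] = {}
        for e in net.events_at(t):
            for a, b in ((e.u, e.v), (e.v, e.u)):
                if a not in arrival:
                    continue
                # the source departs at >= t0; relays need strictly later events
                usable = t >= t0 if a == source else t > arrival[a]
                if not usable:
                    continue
                if b in arrival and arrival[b] < t:
                    continue  # already reached earlier
                contributions.setdefault(b, {})[a] = sigma[a]
        for b, srcs in contributions.items():
            if b not in arrival:
                arrival[b] = t
                sigma[b] = sum(srcs.values())
                preds[b] = set(srcs)
            elif arrival[b] == t and b != source:
                sigma[b] += sum(v for a, v in srcs.items() if a not in preds[b])
                preds[b] |= set(srcs)
    return arrival, sigma, preds


def earliest_arrival(net: TemporalNetwork, source: str, t0: int | None = None
                     ) -> dict[str, float]:
    """Earliest arrival time at every node departing from *source* at >= t0.

    Unreachable nodes map to ``math.inf``; ``arrival[source] == t0``.
    """
    t0 = net.t_start if t0 is None else t0
    arrival, _, _ = _forward_sweep(net, source, t0)
    return {n: arrival.get(n, INF) for n in net.nodes}


def temporal_distance(net: TemporalNetwork, u: str, v: str,
                      t0: int | None = None) -> float:
    """Snapshots needed to reach *v* from *u* departing at t0 (inf if never)."""
    net._require_node(v)
    t0 = net.t_start if t0 is None else t0
    if u == v:
        net._require_node(u)
        return 0
    arr = earliest_arrival(net, u, t0)[v]
    return INF if arr == INF else arr - t0


def count_shortest_temporal_paths(net: TemporalNetwork, u: str, v: str,
                                  t0: int | None = None):
    """Count time-respecting paths from *u* to *v* achieving earliest arrival.

    Returns ``(distance, n_paths, through)`` where ``through[x]`` is the
    number of those paths with *x* as an intermediary (excluding endpoints).
    Unreachable pairs give ``(inf, 0, all-zero)``.
    """
    if u == v:
        raise ValueError("endpoints must differ")
    net._require_node(v)
    t0 = net.t_start if t0 is None else t0
    arrival, sigma, preds = _forward_sweep(net, u, t0)
    through = {n: 0 for n in net.nodes}
    if v not in arrival:
        return INF, 0, through
    # suffix path counts on the shortest-path DAG, from v backwards
    to_v: dict[str, int] = {v: 1}
    order = sorted(arrival, key=lambda n: -arrival[n])
    relevant = {v}
    for w in order:
        if w not in relevant:
            continue
        for p in preds[w]:
            to_v[p] = to_v.get(p, 0) + to_v[w]
            relevant.add(p)
    for x in net.nodes:
        if x in (u, v):
            continue
        through[x] = sigma.get(x, 0) * to_v.get(x, 0)
    return arrival[v] - t0, sigma[v], through


def reachable_set(net: TemporalNetwork, source: str, t0: int | None = None
                  ) -> set[str]:
    """All nodes reachable by a time-respecting path (always contains source)."""
    t0 = net.t_start if t0 is None else t0
    arr = earliest_arrival(net, source, t0)
    return {n for n, a in arr.items() if a != INF}


def brandes_dependencies(net: TemporalNetwork, source: str, t0: int) -> dict[str, float]:
    """Per-node sums of shortest-path fractions for one source (Brandes).

    For every target v reachable from the source, adds sigma_sv(x)/sigma_sv
    to x's total.  Used by temporal betweenness.
    """
    arrival, sigma, preds = _forward_sweep(net, source, t0)
    delta = {n: 0.0 for n in arrival}
    for w in sorted(arrival, key=lambda n: -arrival[n]):
        for p in preds[w]:
            delta[p] += sigma[p] / sigma[w] * (1.0 + delta[w])
    delta.pop(source, None)
    return delta
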