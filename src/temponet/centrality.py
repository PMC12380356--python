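"""Node centrality measures for temporal contact networks.

Three cycle/neighbourhood-based temporal measures:

* **TSCR** (temporal supra-cycle ratio) — for node i, the sum over cycle
  co-members j of ``AC_ij / AC_jj`` computed from the temporal base-cycle
  matrix (plus 1 for i's own membership).  Nodes sharing many cycles with
  well-cycled neighbours score high.
* **TSLI** (temporal semi-local integration) — temporal degree plus, for
  every incident aggregate edge, a term
  ``lambda(e) * |d_i + d_j - 2 w(i,j)| * w(i,j) * d_i / (d_i + d_j)``
  combining the edge's cycle participation ``lambda(e) = P(e) + 1`` and its
  total active time w(i,j).
* **TSLC** (temporal semi-local centrality) — the number of distinct
  second-order neighbours reachable forward in time: nodes i for which
  some intermediary i' has a contact (i, i') strictly before a contact
  (i', j).

Plus four comparison measures: temporal degree deviation (TDD), static
semi-local centrality (SCL), temporal betweenness (TB) and harmonic
temporal closeness (TC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .cycles import BaseCycle, cycle_matrix, cycles_at_time, edge_cycle_count
from .graph import (
    StaticAggregate,
    TemporalNetwork,
    aggregate,
    temporal_degree,
    temporal_neighbors,
)
from .paths import brandes_dependencies, earliest_arrival

__all__ = [
    "CentralityScores",
    "tscr",
    "tsli",
    "tslc",
    "tdd",
    "scl",
    "temporal_betweenness",
    "temporal_closeness",
    "rank_nodes",
    "all_measures",
]

MEASURES = ("TSCR", "TSLI", "TSLC", "TDD", "SCL", "TB", "TC")


@dataclass
class CentralityScores:
    """A named score per node plus the conventions used to compute them."""

    measure: str
    scores: dict[str, float]
    params: dict = field(default_factory=dict)

    def __getitem__(self, node: str) -> float:
        return self.scores[node]

    def vector(self, order) -> list[float]:
        return [self.scores[n] for n in order]


def _tscr_from_matrix(cm) -> dict[str, float]:
    out = {}
    ac = cm.AC
    for a, i in enumerate(cm.order):
        total = 0.0
        for b in range(len(cm.order)):
            if ac[a, b] > 0:
                total += ac[a, b] / ac[b, b]
        out[i] = total
    return out


def tscr(net: TemporalNetwork, cycles: list[BaseCycle],
         aggregation: str = "final_matrix") -> CentralityScores:
    """Temporal supra-cycle ratio.

    ``final_matrix`` (default) evaluates the cycle-ratio sum on the
    full-horizon cycle matrix.  ``cumulative_sum`` recomputes the sum on the
    cumulative cycle matrix of every snapshot and averages over the
    snapshots with at least one completed cycle; the two modes coincide
    when all cycles complete at the first snapshot.  Nodes on no cycle
    score 0.
    """
    for c in cycles:
        if not c.node_set <= set(net.nodes):
            raise ValueError("cycles reference nodes outside the network")
    if aggregation == "final_matrix":
        scores = _tscr_from_matrix(cycle_matrix(cycles, net.nodes))
    elif aggregation == "cumulative_sum":
        sums = {n: 0.0 for n in net.nodes}
        steps = 0
        for t in range(net.t_start, net.t_end + 1):
            present = cycles_at_time(cycles, t)
            if not present:
                continue
            steps += 1
            for n, v in _tscr_from_matrix(cycle_matrix(present, net.nodes)).items():
                sums[n] += v
        scores = {n: (v / steps if steps else 0.0) for n, v in sums.items()}
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return CentralityScores("TSCR", scores, {"aggregation": aggregation})


def tsli(net: TemporalNetwork, cycles: list[BaseCycle],
         degree_mode: str = "distinct_neighbors") -> CentralityScores:
    """Temporal semi-local integration (degree plus weighted edge terms)."""
    agg = aggregate(net)
    deg = {n: float(temporal_degree(net, n, mode=degree_mode)) for n in net.nodes}
    scores = dict(deg)
    for (u, v), w in agg.edge_weights.items():
        lam = edge_cycle_count(cycles, (u, v)) + 1
        du, dv = deg[u], deg[v]
        base = lam * abs(du + dv - 2.0 * w) * w
        scores[u] += base * du / (du + dv)
        scores[v] += base * dv / (du + dv)
    return CentralityScores("TSLI", scores, {"degree_mode": degree_mode})


def tslc(net: TemporalNetwork) -> CentralityScores:
    """Temporal semi-local centrality: distinct time-respecting second-order
    neighbours.  Node i counts for j when some intermediary i' has a
    contact (i, i') strictly before a contact (i', j); i = j is excluded.
    """
    scores = {}
    sets = tslc_sets(net)
    for n in net.nodes:
        scores[n] = float(len(sets[n]))
    return CentralityScores("TSLC", scores, {})


def tslc_sets(net: TemporalNetwork) -> dict[str, set[str]]:
    """The second-order in-neighbour set behind each TSLC count."""
    out: dict[str, set[str]] = {}
    for j in net.nodes:
        second: set[str] = set()
        for ip in temporal_neighbors(net, j):
            latest_in = max(net.edge_times(ip, j))
            for i in temporal_neighbors(net, ip):
                if i == j:
                    continue
                if min(net.edge_times(i, ip)) < latest_in:
                    second.add(i)
        out[j] = second
    return out


def tdd(net: TemporalNetwork) -> CentralityScores:
    """Temporal degree deviation: mean squared gap between the snapshot
    degree and the static aggregate degree (no square root)."""
    T = net.n_snapshots
    if T == 0:
        raise ValueError("network has no snapshots")
    agg = aggregate(net)
    static = {n: agg.degree(n) for n in net.nodes}
    sq = {n: 0.0 for n in net.nodes}
    per_t_deg: dict[int, dict[str, int]] = {}
    for e in net.events:
        d = per_t_deg.setdefault(e.t, {})
        d[e.u] = d.get(e.u, 0) + 1
        d[e.v] = d.get(e.v, 0) + 1
    for t in range(net.t_start, net.t_end + 1):
        d = per_t_deg.get(t, {})
        for n in net.nodes:
            sq[n] += (d.get(n, 0) - static[n]) ** 2
    return CentralityScores("TDD", {n: v / T for n, v in sq.items()}, {"T": T})


def scl(agg: StaticAggregate) -> CentralityScores:
    """Static semi-local centrality: the number of 2-walks from each node
    on the aggregate (sum of neighbours' degrees)."""
    deg = {n: agg.degree(n) for n in agg.nodes}
    scores = {n: 0.0 for n in agg.nodes}
    for n in agg.nodes:
        scores[n] = float(sum(deg[j] for j in agg.neighbors(n)))
    return CentralityScores("SCL", scores, {})


def temporal_betweenness(net: TemporalNetwork, t0: int | None = None
                         ) -> CentralityScores:
    """Shortest-temporal-path betweenness.

    Sums sigma_st(v)/sigma_st over ordered source-target pairs for a single
    global departure time (default: the start of the observation window).
    Raw (unnormalized) values; pairs with no time-respecting path contribute
    nothing.
    """
    t0 = net.t_start if t0 is None else t0
    totals = {n: 0.0 for n in net.nodes}
    for s in net.nodes:
        for n, d in brandes_dependencies(net, s, t0).items():
            totals[n] += d
    return CentralityScores("TB", totals, {"t0": t0, "pairs": "ordered"})


def temporal_closeness(net: TemporalNetwork, t0: int | None = None
                       ) -> CentralityScores:
    """Harmonic temporal closeness: sum over other nodes of 1/tau'(i, j)
    where tau' = max(tau, 1) floors direct same-snapshot contacts at one
    time step (so the reciprocal is defined) and 1/inf = 0."""
    t0 = net.t_start if t0 is None else t0
    scores = {}
    for i in net.nodes:
        arr = earliest_arrival(net, i, t0)
        total = 0.0
        for j, a in arr.items():
            if j == i or a == math.inf:
                continue
            total += 1.0 / max(a - t0, 1)
        scores[i] = total
    return CentralityScores("TC", scores, {"t0": t0, "form": "harmonic"})


def rank_nodes(scores: CentralityScores, top_fraction: float = 1.0) -> list[str]:
    """Nodes by descending score, ties broken by the canonical node order;
    returns the top ``ceil(top_fraction * N)``."""
    if not scores.scores:
        raise ValueError("empty score mapping")
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must lie in (0, 1]")
    ordered = sorted(scores.scores, key=lambda n: (-scores.scores[n], n))
    k = math.ceil(top_fraction * len(ordered))
    return ordered[:k]


def all_measures(net: TemporalNetwork, root: str | None = None,
                 measures=MEASURES) -> dict[str, CentralityScores]:
    """Compute a set of measures with shared cycle enumeration."""
    from .cycles import enumerate_base_cycles

    cycles = None
    out: dict[str, CentralityScores] = {}
    for m in measures:
        mu = m.upper()
        if mu in ("TSCR", "TSLI") and cycles is None:
            cycles = enumerate_base_cycles(net, root)
        if mu == "TSCR":
            out[mu] = tscr(net, cycles)
        elif mu == "TSLI":
            out[mu] = tsli(net, cycles)
        elif mu == "TSLC":
            out[mu] = tslc(net)
        elif mu == "TDD":
            out[mu] = tdd(net)
        elif mu == "SCL":
            out[mu] = scl(aggregate(net))
        elif mu == "TB":
            out[mu] = temporal_betweenness(net)
        elif mu == "TC":
            out[mu] = temporal_closeness(net)
        else:
            raise ValueError(f"unknown measure {m!r}")
        if mu in ("TSCR", "TSLI"):
            out[mu].params["root"] = root if root is not None else (
                net.nodes[0] if net.nodes else None)
    return out
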