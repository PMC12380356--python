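"""Synthetic temporal networks and the ten-node worked example.

Three generators stand in for empirical face-to-face contact data so that
every pipeline stage is testable without downloads:

* ``snapshot_er`` — every snapshot is an independent Erdos-Renyi graph
  G(n, p): dense-in-time, memoryless contacts.
* ``activity_driven`` — each node carries an activity rate; an active node
  emits a small star of contacts per snapshot.  Produces the heavy-tailed
  temporal degrees typical of conference-style data.
* ``planted_cycles`` — embeds temporally admissible triangles (edges laid
  down in increasing time order plus a later chord) in sparse noise, with
  the planted node sets returned as ground truth.

``worked_example`` builds the canonical 10-node example network used
throughout the documentation and tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .graph import ContactEvent, TemporalNetwork

__all__ = ["SynthConfig", "generate", "worked_example", "WORKED_EXAMPLE_EDGES",
           "shuffle_times"]

#: The 15 undirected edges of the worked example (text-derived topology).
WORKED_EXAMPLE_EDGES = (
    ("V0", "V1"), ("V0", "V2"), ("V0", "V7"), ("V1", "V3"), ("V2", "V3"),
    ("V2", "V5"), ("V2", "V7"), ("V4", "V6"), ("V4", "V7"), ("V4", "V8"),
    ("V5", "V6"), ("V6", "V7"), ("V6", "V8"), ("V6", "V9"), ("V8", "V9"),
)


@dataclass
class SynthConfig:
    """Generator settings; all randomness flows from ``rng_seed``."""

    n_nodes: int = 30
    n_snapshots: int = 50
    model: str = "snapshot_er"
    edge_prob: float = 0.05
    activity_exponent: float = 2.5
    contacts_per_active: int = 2
    n_planted: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.n_snapshots < 1:
            raise ValueError("n_nodes and n_snapshots must be positive")
        if not (0 <= self.edge_prob <= 1):
            raise ValueError("edge_prob must lie in [0, 1]")


def _node_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"n{str(k).zfill(width)}" for k in range(n)]


def generate(config: SynthConfig):
    """Build a synthetic temporal network from a config.

    Returns a ``TemporalNetwork``; for ``planted_cycles`` a tuple
    ``(network, planted)`` where ``planted`` is a list of frozensets of the
    planted cycle node sets.
    """
    rng = np.random.default_rng(config.rng_seed)
    names = _node_names(config.n_nodes)
    if config.model == "snapshot_er":
        events = []
        for t in range(config.n_snapshots):
            for a in range(config.n_nodes):
                for b in range(a + 1, config.n_nodes):
                    if rng.random() < config.edge_prob:
                        events.append(ContactEvent(names[a], names[b], t))
        return TemporalNetwork(events, nodes=names,
                               t_start=0, t_end=config.n_snapshots - 1)
    if config.model == "activity_driven":
        # activity rates from a bounded Pareto-like law in [0.03, 1]
        raw = rng.pareto(config.activity_exponent, config.n_nodes) + 1.0
        act = np.clip(0.03 * raw, 0.03, 1.0)
        events = []
        for t in range(config.n_snapshots):
            for a in range(config.n_nodes):
                if rng.random() < act[a]:
                    others = [b for b in range(config.n_nodes) if b != a]
                    k = min(config.contacts_per_active, len(others))
                    for b in rng.choice(others, size=k, replace=False):
                        events.append(ContactEvent(names[a], names[int(b)], t))
        return TemporalNetwork(events, nodes=names,
                               t_start=0, t_end=config.n_snapshots - 1)
    if config.model == "planted_cycles":
        if config.n_snapshots < 4:
            raise ValueError("planted_cycles needs at least 4 snapshots")
        if config.n_nodes < 3 * config.n_planted:
            raise ValueError("planted_cycles needs >= 3 nodes per planted cycle")
        events = []
        planted = []
        # node-disjoint trios so each planted cycle is recoverable exactly
        chosen = rng.choice(config.n_nodes, size=3 * config.n_planted,
                            replace=False)
        for k in range(config.n_planted):
            trio = chosen[3 * k: 3 * k + 3]
            a, b, c = (names[int(x)] for x in sorted(trio))
            t0 = int(rng.integers(0, config.n_snapshots - 3))
            # tree path laid down in time order, chord strictly later
            events += [ContactEvent(a, b, t0), ContactEvent(b, c, t0 + 1),
                       ContactEvent(a, c, t0 + 3)]
            planted.append(frozenset((a, b, c)))
        # sparse background noise
        for t in range(config.n_snapshots):
            for a in range(config.n_nodes):
                for b in range(a + 1, config.n_nodes):
                    if rng.random() < config.edge_prob / 10:
                        events.append(ContactEvent(names[a], names[b], t))
        net = TemporalNetwork(events, nodes=names,
                              t_start=0, t_end=config.n_snapshots - 1)
        return net, planted
    raise ValueError(f"unknown model {config.model!r}")


def _default_times() -> dict[tuple[str, str], list[int]]:
    payload = json.loads(
        resources.files("temponet")
        .joinpath("data/worked_example_times_synthetic.json")
        .read_text()
    )
    return {tuple(k.split(",")): v for k, v in payload["edges"].items()}


def worked_example(times: dict[tuple[str, str], list[int]] | None = None
                   ) -> TemporalNetwork:
    """The 10-node worked example (nodes V0..V9, 15 edges, 6 base cycles).

    ``times`` maps each of the 15 undirected edges to its activation
    snapshots; by default a bundled synthetic reconstruction is used (see
    ``data/worked_example_times_synthetic.json``).  The edge set is fixed;
    supplying a different one raises with the symmetric difference.
    """
    if times is None:
        times = _default_times()
    given = {tuple(sorted(e)) for e in times}
    expect = {tuple(sorted(e)) for e in WORKED_EXAMPLE_EDGES}
    if given != expect:
        missing = sorted(expect - given)
        extra = sorted(given - expect)
        raise ValueError(
            f"edge set mismatch: missing {missing}, unexpected {extra}"
        )
    events = []
    for (u, v), ts in times.items():
        for t in ts:
            events.append(ContactEvent(u, v, int(t)))
    return TemporalNetwork(events)


# Backwards-friendly alias matching the figure name used in discussions.
fig1_fixture = worked_example


def shuffle_times(net: TemporalNetwork, rng_seed: int = 0) -> TemporalNetwork:
    """Null model: permute event times uniformly among events.

    The aggregate topology and the multiset of activation times are
    preserved; temporal order is destroyed.  Coinciding (pair, time)
    duplicates created by the permutation are re-drawn, so the event count
    is preserved as well.
    """
    rng = np.random.default_rng(rng_seed)
    pairs = [e.pair for e in net.events]
    times = [e.t for e in net.events]
    for _ in range(200):
        perm = rng.permutation(len(times))
        shuffled = {(pairs[k], times[int(perm[k])]) for k in range(len(times))}
        if len(shuffled) == len(times):
            return TemporalNetwork(
                (ContactEvent(u, v, t) for (u, v), t in shuffled),
                nodes=net.nodes, t_start=net.t_start, t_end=net.t_end)
    # fall back: per-pair time reassignment without replacement
    return TemporalNetwork(
        (ContactEvent(pairs[k][0], pairs[k][1], times[k]) for k in range(len(times))),
        nodes=net.nodes, t_start=net.t_start, t_end=net.t_end)
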