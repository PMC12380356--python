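"""The three temporal measures and the four baselines.

Worked-example anchor values for TSCR come from evaluating the cycle-ratio
sum on the published cycle list by hand (exact fractions); SCL is checked
against the adjacency-square oracle; small hand-evaluated networks cover
the formulas' edge cases.
"""

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from temponet import (
    TemporalNetwork,
    aggregate,
    enumerate_base_cycles,
    rank_nodes,
    scl,
    tdd,
    temporal_betweenness,
    temporal_closeness,
    tscr,
    tsli,
    tslc,
)
from temponet.centrality import tslc_sets

# hand-evaluated cycle-ratio sums from the published six-cycle list
EXAMPLE_TSCR = {
    "V0": Fraction(4), "V1": Fraction(17, 6), "V2": Fraction(71, 12),
    "V3": Fraction(17, 6), "V4": Fraction(7, 3), "V5": Fraction(23, 12),
    "V6": Fraction(6), "V7": Fraction(25, 6), "V8": Fraction(3),
    "V9": Fraction(7, 4),
}


class TestTSCR:
    def test_acyclic_network_all_zero(self):
        net = TemporalNetwork([("a", "b", 0), ("b", "c", 1)])
        s = tscr(net, enumerate_base_cycles(net))
        assert set(s.scores.values()) == {0.0}

    def test_example_matches_hand_matrix(self, example_net, example_cycles):
        s = tscr(net=example_net, cycles=example_cycles)
        for node, want in EXAMPLE_TSCR.items():
            assert s.scores[node] == pytest.approx(float(want), abs=1e-12)

    def test_example_ordering_v6_then_v2(self, example_net, example_cycles):
        s = tscr(example_net, example_cycles)
        assert rank_nodes(s, 0.2) == ["V6", "V2"]

    def test_single_triangle_scores_three_each(self):
        net = TemporalNetwork([("a", "b", 0), ("b", "c", 1), ("a", "c", 2)])
        s = tscr(net, enumerate_base_cycles(net))
        assert all(v == pytest.approx(3.0) for v in s.scores.values())

    def test_cumulative_mode_equals_final_on_instant_cycles(self):
        # all cycles complete at the first snapshot -> modes coincide
        net = TemporalNetwork([("a", "b", 0), ("b", "c", 0), ("a", "c", 0)])
        cycles = enumerate_base_cycles(net)
        final = tscr(net, cycles, aggregation="final_matrix").scores
        cumulative = tscr(net, cycles, aggregation="cumulative_sum").scores
        assert final == cumulative

    def test_score_at_least_one_on_cycle_nodes(self, example_net, example_cycles):
        s = tscr(example_net, example_cycles)
        on_cycles = set().union(*(c.node_set for c in example_cycles))
        for n in example_net.nodes:
            if n in on_cycles:
                assert s.scores[n] >= 1.0
            else:
                assert s.scores[n] == 0.0


class TestTSLI:
    def test_isolated_node_scores_zero(self):
        net = TemporalNetwork([("a", "b", 0)], nodes=["a", "b", "z"])
        s = tsli(net, enumerate_base_cycles(net))
        assert s.scores["z"] == 0.0

    def test_single_edge_hand_value(self):
        # one edge active twice, no cycles: lambda=1, d=1 each, w=2
        # I(a,b) = 1 * |1+1-4| * 2 * (1/2) = 2 ; I(a) = 1 + 2 = 3
        net = TemporalNetwork([("a", "b", 0), ("a", "b", 1)])
        s = tsli(net, [])
        assert s.scores["a"] == pytest.approx(3.0)
        assert s.scores["b"] == pytest.approx(3.0)

    def test_example_ordering_v7_then_v6(self, example_net, example_cycles):
        s = tsli(example_net, example_cycles)
        top = rank_nodes(s, 1.0)
        assert top[0] == "V7" and top[1] == "V6"

    def test_score_dominates_degree(self, example_net, example_cycles):
        from temponet import temporal_degree

        s = tsli(example_net, example_cycles)
        for n in example_net.nodes:
            assert s.scores[n] >= temporal_degree(example_net, n)


class TestTSLC:
    def test_single_snapshot_network_all_zero(self):
        net = TemporalNetwork([("a", "b", 4), ("b", "c", 4), ("c", "d", 4)])
        assert set(tslc(net).scores.values()) == {0.0}

    def test_chain_hand_case(self):
        net = TemporalNetwork([("a", "b", 1), ("b", "c", 2)])
        s = tslc(net)
        assert s.scores["c"] == 1  # {a} via b
        assert s.scores["a"] == 0  # (b,c) at t=2 is after (a,b), not before

    def test_example_v7_second_order_set(self, example_net):
        sets = tslc_sets(example_net)
        assert sets["V7"] == {"V0", "V1", "V2", "V5", "V6", "V8"}
        assert tslc(example_net).scores["V7"] == 6

    def test_example_v7_above_v6(self, example_net):
        s = tslc(example_net).scores
        assert s["V7"] == 6 and s["V6"] == 5

    def test_bounded_by_population(self, rng):
        from .conftest import random_network

        for _ in range(20):
            net = random_network(rng)
            for v in tslc(net).scores.values():
                assert 0 <= v <= len(net.nodes) - 1


class TestTDD:
    def test_steady_node_scores_zero(self):
        # a-b active at every snapshot: snapshot degree == static degree
        net = TemporalNetwork([("a", "b", 0), ("a", "b", 1), ("a", "b", 2)])
        assert tdd(net).scores["a"] == 0.0

    def test_hand_value(self):
        # D(a)=2, T=2, each snapshot degree 1 -> ((1)^2 + (1)^2)/2 = 1
        net = TemporalNetwork([("a", "b", 1), ("a", "c", 2)], t_start=1, t_end=2)
        assert tdd(net).scores["a"] == pytest.approx(1.0)

    def test_isolated_node_zero(self):
        net = TemporalNetwork([("a", "b", 0)], nodes=["a", "b", "z"])
        assert tdd(net).scores["z"] == 0.0


class TestSCL:
    def test_path_graph_hand_value(self):
        net = TemporalNetwork([("a", "b", 0), ("b", "c", 1)])
        s = scl(aggregate(net))
        assert s.scores["a"] == 2  # walks a-b-a and a-b-c

    def test_star_center(self):
        net = TemporalNetwork([("c", f"l{k}", 0) for k in range(4)])
        assert scl(aggregate(net)).scores["c"] == 4

    def test_matches_adjacency_square_oracle(self, example_net):
        g = aggregate(example_net).to_networkx()
        order = sorted(g.nodes)
        a = nx.to_numpy_array(g, nodelist=order, weight=None)
        two_walks = (a @ a).sum(axis=1)
        s = scl(aggregate(example_net))
        for k, n in enumerate(order):
            assert s.scores[n] == pytest.approx(two_walks[k])


class TestBetweennessCloseness:
    def test_chain_middle_betweenness(self):
        net = TemporalNetwork([("a", "b", 1), ("b", "c", 2)])
        s = temporal_betweenness(net)
        # ordered pairs (a,c) and (c,a): c->a has no time-respecting path
        assert s.scores["b"] == pytest.approx(1.0)
        assert s.scores["a"] == 0.0

    def test_single_snapshot_star_all_zero(self):
        net = TemporalNetwork([("c", f"l{k}", 3) for k in range(3)])
        assert set(temporal_betweenness(net).scores.values()) == {0.0}

    def test_closeness_floor_convention(self):
        # tau(a,b)=0 floored to 1; tau(a,c)=2 -> TC(a) = 1 + 1/2
        net = TemporalNetwork([("a", "b", 1), ("b", "c", 3)], t_start=1)
        assert temporal_closeness(net).scores["a"] == pytest.approx(1.5)

    def test_edgeless_closeness_zero(self):
        net = TemporalNetwork(nodes=["a", "b", "c"])
        assert set(temporal_closeness(net).scores.values()) == {0.0}

    def test_symmetric_pair_equal_closeness(self):
        net = TemporalNetwork([("a", "b", 2)])
        s = temporal_closeness(net).scores
        assert s["a"] == s["b"]


class TestRanking:
    def test_ties_break_canonically(self):
        from temponet.centrality import CentralityScores

        s = CentralityScores("X", {"b": 1.0, "a": 1.0, "c": 1.0})
        assert rank_nodes(s, 0.5) == ["a", "b"]

    def test_full_fraction_is_permutation(self, example_net, example_cycles):
        s = tscr(example_net, example_cycles)
        assert sorted(rank_nodes(s, 1.0)) == sorted(example_net.nodes)

    def test_empty_scores_rejected(self):
        from temponet.centrality import CentralityScores

        with pytest.raises(ValueError):
            rank_nodes(CentralityScores("X", {}), 0.5)


@pytest.mark.parametrize(
    "mapping,measures",
    [
        # order-preserving relabeling: every measure, including the
        # tie-break-sensitive cycle measures, must commute with it
        ({"a": "p", "b": "q", "c": "r", "d": "s"},
         ("TSCR", "TSLI", "TSLC", "TDD", "SCL", "TB", "TC")),
        # arbitrary relabeling: tie-break-free measures must still commute
        ({"a": "p", "b": "s", "c": "q", "d": "r"},
         ("TSLC", "TDD", "SCL", "TB", "TC")),
    ],
)
def test_label_equivariance(mapping, measures):
    """Permuting node labels permutes the score vectors identically."""
    from temponet.centrality import all_measures

    events = [("a", "b", 0), ("b", "c", 1), ("a", "c", 3), ("c", "d", 2),
              ("b", "d", 4), ("a", "d", 1)]
    net = TemporalNetwork(events)
    relabeled = TemporalNetwork([(mapping[u], mapping[v], t) for u, v, t in events])
    base = all_measures(net, measures=measures)
    perm = all_measures(relabeled, measures=measures)
    for m in base:
        for n, v in base[m].scores.items():
            assert perm[m].scores[mapping[n]] == pytest.approx(v), m
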