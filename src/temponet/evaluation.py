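"""Robustness percolation curves and cross-measure correlation analysis.

Robustness is read out as the size (node count) of the largest connected
component of the static aggregate after deleting the top-ranked fraction
of nodes; nested removals by a fixed ranking give a non-increasing curve.
A temporal variant (largest temporal-reachability set) is available behind
a flag.  Measure similarity uses pairwise Pearson correlation with
two-sided p-values; constant score vectors make the correlation undefined
(rendered as the marker ``"U"`` in exports).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .centrality import CentralityScores, rank_nodes
from .graph import TemporalNetwork, aggregate
from .paths import reachable_set

__all__ = ["RobustnessCurve", "CorrelationMatrix", "robustness_curve",
           "correlation_matrix"]

UNDEFINED = "U"


@dataclass
class RobustnessCurve:
    fractions: tuple[float, ...]
    smax: tuple[int, ...]

    def as_rows(self):
        return list(zip(self.fractions, self.smax))


def _largest_cc(net: TemporalNetwork, removed: set[str], temporal: bool) -> int:
    kept = [n for n in net.nodes if n not in removed]
    if not kept:
        return 0
    sub = net.remove_nodes(removed)
    if temporal:
        return max(len(reachable_set(sub, s)) for s in sub.nodes)
    g = aggregate(sub).to_networkx()
    return max(len(c) for c in nx.connected_components(g))


def robustness_curve(net: TemporalNetwork, scores: CentralityScores,
                     fractions, temporal: bool = False) -> RobustnessCurve:
    """S_max after removing the top ceil(f*N) ranked nodes, per fraction f."""
    if not net.nodes:
        raise ValueError("empty network")
    fr = tuple(fractions)
    if any(not (0 <= f < 1) for f in fr):
        raise ValueError("fractions must lie in [0, 1)")
    if list(fr) != sorted(fr):
        raise ValueError("fractions must be sorted ascending")
    n = len(net.nodes)
    full_rank = rank_nodes(scores, 1.0)
    sizes = []
    for f in fr:
        k = math.ceil(f * n) if f > 0 else 0
        sizes.append(_largest_cc(net, set(full_rank[:k]), temporal))
    return RobustnessCurve(fractions=fr, smax=tuple(sizes))


@dataclass
class CorrelationMatrix:
    measures: tuple[str, ...]
    r: np.ndarray  # NaN marks undefined entries
    p: np.ndarray

    def entry(self, a: str, b: str):
        i, j = self.measures.index(a), self.measures.index(b)
        r = self.r[i, j]
        return UNDEFINED if np.isnan(r) else float(r)

    def as_frame(self):
        import pandas as pd

        disp = [[UNDEFINED if np.isnan(v) else round(float(v), 4) for v in row]
                for row in self.r]
        return pd.DataFrame(disp, index=self.measures, columns=self.measures)


def correlation_matrix(score_sets: list[CentralityScores]) -> CorrelationMatrix:
    """Pairwise Pearson r and two-sided p-values across measures.

    All score sets must cover the same node set (>= 3 nodes).  A constant
    vector yields NaN for its whole row and column (the undefined marker).
    """
    if not score_sets:
        raise ValueError("need at least one score set")
    order = tuple(sorted(score_sets[0].scores))
    if len(order) < 3:
        raise ValueError("need at least 3 nodes for correlation")
    for s in score_sets[1:]:
        if tuple(sorted(s.scores)) != order:
            raise ValueError("score sets cover different node sets")
    labels = tuple(s.measure for s in score_sets)
    vecs = [np.asarray(s.vector(order), dtype=float) for s in score_sets]
    m = len(vecs)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i, m):
            if np.ptp(vecs[i]) == 0 or np.ptp(vecs[j]) == 0:
                continue  # undefined: Pearson needs variability
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            res = stats.pearsonr(vecs[i], vecs[j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return CorrelationMatrix(measures=labels, r=r, p=p)
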