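"""Discrete-time SIR dynamics on temporal networks and the evaluation
experiments built on them.

The epidemic unfolds over the recorded contact stream: at every snapshot,
each susceptible node in contact with an infectious node becomes infected
with probability ``beta`` (independently per infectious contact), and each
infectious node recovers with probability ``gamma``.  Transmission is
synchronous — it is evaluated on the states at the start of the snapshot,
so infections take effect from the next snapshot and there is no multi-hop
spread within one snapshot — and recoveries are applied after
transmission.  Recovery is absorbing.

The diffusion-speed summary is the Omega curve: the number of newly
infected nodes per snapshot averaged over Monte-Carlo runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .centrality import CentralityScores, rank_nodes
from .graph import TemporalNetwork

__all__ = [
    "SIRParams",
    "SIRRun",
    "OmegaCurve",
    "sir_run",
    "omega",
    "isolation_experiment",
    "seeding_experiment",
]


@dataclass
class SIRParams:
    """Transmission/recovery probabilities per snapshot, the seed set, the
    number of Monte-Carlo runs M and the base RNG seed."""

    beta: float = 0.5
    gamma: float = 0.005
    seeds: tuple[str, ...] = ()
    runs: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.beta <= 1 and 0 <= self.gamma <= 1):
            raise ValueError("beta and gamma must lie in [0, 1]")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        self.seeds = tuple(self.seeds)


@dataclass
class SIRRun:
    """One realisation: per-snapshot states, new-infection counts, final tally."""

    times: tuple[int, ...]
    state_timeline: list[dict[str, str]]
    new_infections: np.ndarray
    final_sizes: dict[str, int]

    @property
    def ever_infected(self) -> int:
        return self.final_sizes["I"] + self.final_sizes["R"]


@dataclass
class OmegaCurve:
    """Mean newly-infected-per-snapshot curve across runs."""

    times: tuple[int, ...]
    omega: np.ndarray
    runs: int
    peak_value: float = field(init=False)
    peak_time: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.omega):
            k = int(np.argmax(self.omega))
            self.peak_value = float(self.omega[k])
            self.peak_time = int(self.times[k])
        else:
            self.peak_value, self.peak_time = 0.0, 0

    @property
    def extinction_time(self) -> int | None:
        """First snapshot after which omega stays zero (None if never positive)."""
        nz = np.nonzero(self.omega)[0]
        if len(nz) == 0:
            return None
        last = nz[-1]
        return int(self.times[last + 1]) if last + 1 < len(self.times) else None


def sir_run(net: TemporalNetwork, params: SIRParams,
            rng: np.random.Generator | None = None) -> SIRRun:
    """One synchronous SIR realisation over the contact stream."""
    nodes = set(net.nodes)
    seeds = set(params.seeds)
    if not seeds:
        raise ValueError("seed set must not be empty")
    if not seeds <= nodes:
        raise ValueError(f"seeds outside the network: {sorted(seeds - nodes)}")
    rng = np.random.default_rng(params.rng_seed) if rng is None else rng
    state = {n: ("I" if n in seeds else "S") for n in net.nodes}
    times = tuple(range(net.t_start, net.t_end + 1))
    timeline: list[dict[str, str]] = []
    new_inf = np.zeros(len(times), dtype=float)
    for k, t in enumerate(times):
        infected_now: set[str] = set()
        for e in net.events_at(t):
            for a, b in ((e.u, e.v), (e.v, e.u)):
                if state[a] == "I" and state[b] == "S" and b not in infected_now:
                    if rng.random() < params.beta:
                        infected_now.add(b)
        recovered_now = {
            n for n, s in state.items()
            if s == "I" and rng.random() < params.gamma
        }
        for n in infected_now:
            state[n] = "I"
        for n in recovered_now:
            state[n] = "R"
        new_inf[k] = len(infected_now)
        timeline.append(dict(state))
    final = {s: sum(1 for v in state.values() if v == s) for s in "SIR"}
    return SIRRun(times=times, state_timeline=timeline,
                  new_infections=new_inf, final_sizes=final)


def _child_rngs(rng_seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(rng_seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def omega(net: TemporalNetwork, params: SIRParams,
          seed_pool: Sequence[str] | None = None) -> OmegaCurve:
    """Average the new-infection curve over M independent runs.

    If ``seed_pool`` is given, each run seeds a single node drawn uniformly
    from the pool; otherwise ``params.seeds`` is used for every run.
    """
    times = tuple(range(net.t_start, net.t_end + 1))
    total = np.zeros(len(times), dtype=float)
    for rng in _child_rngs(params.rng_seed, params.runs):
        run_params = params
        if seed_pool is not None:
            pick = seed_pool[int(rng.integers(len(seed_pool)))]
            run_params = replace(params, seeds=(pick,))
        total += sir_run(net, run_params, rng=rng).new_infections
    return OmegaCurve(times=times, omega=total / params.runs, runs=params.runs)


@dataclass
class PeakSummary:
    """Peak of the per-run new-infection maxima with a normal-approximation CI."""

    mean: float
    ci_low: float
    ci_high: float
    runs: int


def isolation_experiment(net: TemporalNetwork, scores: CentralityScores,
                         remove_fraction: float, params: SIRParams
                         ) -> tuple[OmegaCurve, PeakSummary]:
    """Remove the top-ranked fraction of nodes, then measure epidemic speed.

    Single random seeds are drawn uniformly from the surviving nodes per
    run; the peak summary is the mean per-run peak of new infections with a
    95% normal-approximation confidence interval.
    """
    if not (0 <= remove_fraction < 1):
        raise ValueError("remove_fraction must lie in [0, 1)")
    n = len(net.nodes)
    k = math.ceil(remove_fraction * n) if remove_fraction > 0 else 0
    removed = rank_nodes(scores, k / n) if k else []
    reduced = net.remove_nodes(removed) if removed else net
    survivors = reduced.nodes
    if len(survivors) < 2:
        raise ValueError("removal leaves fewer than 2 nodes")
    times = tuple(range(reduced.t_start, reduced.t_end + 1))
    total = np.zeros(len(times), dtype=float)
    peaks = []
    for rng in _child_rngs(params.rng_seed, params.runs):
        pick = survivors[int(rng.integers(len(survivors)))]
        run = sir_run(reduced, replace(params, seeds=(pick,)), rng=rng)
        total += run.new_infections
        peaks.append(float(run.new_infections.max()) if len(run.new_infections) else 0.0)
    curve = OmegaCurve(times=times, omega=total / params.runs, runs=params.runs)
    peaks_arr = np.asarray(peaks)
    mean = float(peaks_arr.mean())
    se = float(peaks_arr.std(ddof=1) / math.sqrt(len(peaks_arr))) if len(peaks_arr) > 1 else 0.0
    summary = PeakSummary(mean=mean, ci_low=mean - 1.96 * se,
                          ci_high=mean + 1.96 * se, runs=params.runs)
    return curve, summary


def seeding_experiment(net: TemporalNetwork, scores: CentralityScores,
                       top_fraction: float, params: SIRParams) -> OmegaCurve:
    """Seed the top-ranked fraction and spread with transmission probability
    forced to 1 (the seeding benchmark), averaging over M runs."""
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must lie in (0, 1]")
    seeds = tuple(rank_nodes(scores, top_fraction))
    forced = replace(params, beta=1.0, seeds=seeds)
    return omega(net, forced)
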