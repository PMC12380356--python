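# temponet

Critical-node detection in **temporal contact networks**: which individuals
should be isolated to slow an epidemic, seeded to spread information fastest,
or removed to fragment a network?

Empirical face-to-face contact data (SocioPatterns-style RFID recordings,
one contact event per 20 s interval) form a temporal network
𝒢 = (𝒩, ℰ, ℒ): a node set, a stream of undirected events (i, j, t) and the
binary activity indicator ℒ(i, j, t). Static centrality ignores *when*
contacts happen; `temponet` implements three temporal measures that do not,
together with the machinery needed to evaluate them.

## Measures

* **TSCR — temporal supra-cycle ratio.** Enumerate the temporal base cycles:
  chords over an earliest-arrival spanning tree whose closing event comes no
  earlier than the flow reaching both endpoints. With AC_ij the number of
  cycles containing both i and j,

      TSCR(i) = Σ_j  AC_ij / AC_jj      (terms with AC_ij = 0 drop out)

  Nodes sharing many cycles with well-cycled neighbours score high.
* **TSLI — temporal semi-local integration.** Degree plus per-edge terms
  λ(e) · |dᵢ + dⱼ − 2 w(i,j)| · w(i,j) · dᵢ/(dᵢ+dⱼ), where w(i,j) is the
  edge's total active time and λ(e) = P(e) + 1 counts the base cycles through
  the edge: nodes attached to long-active, well-cycled edges matter.
* **TSLC — temporal semi-local centrality.** The number of distinct
  second-order neighbours reachable *forward in time*: i counts for j when
  some intermediary i′ has a contact (i, i′) strictly before a contact (i′, j).

Baselines for comparison: temporal degree deviation (TDD), static semi-local
centrality (SCL), temporal betweenness (TB) and harmonic temporal closeness
(TC).

Evaluation harness: a discrete-time SIR model driven by the recorded contact
stream (transmission probability β per infectious contact per snapshot,
recovery probability γ, synchronous updates) with the diffusion-speed curve
Ω(t) = mean newly-infected-per-snapshot across Monte-Carlo runs; isolation
and seeding experiments; percolation robustness curves S_max(f); and pairwise
Pearson correlation between measures (with an explicit undefined marker for
constant score vectors, e.g. TSCR on cycle-free data).

## Worked example

The bundled ten-node example network (nodes V0..V9, 15 edges, activation
times bundled as data) is the canonical fixture:

```python
from temponet import (worked_example, enumerate_base_cycles, tscr,
                      rank_nodes, SIRParams, isolation_experiment)

net = worked_example()
cycles = enumerate_base_cycles(net, "V0")
for c in cycles:
    print(list(c.node_sequence), "formed at t =", c.formation_time)
s = tscr(net, cycles)
print({n: round(v, 2) for n, v in s.scores.items()})
print(rank_nodes(s, 0.2))
```

prints the six base cycles with their formation times

```
['V0', 'V2', 'V7'] formed at t = 3
['V0', 'V1', 'V3', 'V2'] formed at t = 5
['V2', 'V5', 'V6', 'V7'] formed at t = 5
['V4', 'V6', 'V7'] formed at t = 4
['V4', 'V6', 'V8'] formed at t = 9
['V6', 'V8', 'V9'] formed at t = 10
```

and the cycle-ratio scores

```
{'V0': 4.0, 'V1': 2.83, 'V2': 5.92, 'V3': 2.83, 'V4': 2.33,
 'V5': 1.92, 'V6': 6.0, 'V7': 4.17, 'V8': 3.0, 'V9': 1.75}
['V6', 'V2']
```

V6 sits on four of the six cycles and tops the ranking, followed by V2 with
three. Removing the single top-ranked node before an outbreak
(β = 0.5, γ = 0.005, 100 runs) lowers the peak spreading speed:

```python
p = SIRParams(beta=0.5, gamma=0.005, runs=100, rng_seed=1)
_, peak = isolation_experiment(net, s, 0.1, p)     # remove top 10 %
print(round(peak.mean, 2), [round(peak.ci_low, 2), round(peak.ci_high, 2)])
```

```
1.21 [1.08, 1.34]        # vs 1.56 [1.39, 1.73] on the intact network
```

## Command line

```sh
temponet scores --input contacts.txt --time-unit 20 --measures all --out out/
temponet sir --mode isolate --measure tscr --fraction 0.01 \
         --beta 0.5 --gamma 0.005 --runs 100 --seed 42 --out out/
temponet robustness --fractions 0.1:0.9:0.1 --out out/
temponet correlate --measures all --out out/
temponet synth --model snapshot_er --nodes 100 --snapshots 200 --p 0.01 --seed 7
```

Omitting `--input` runs on the bundled worked example. Contact lists are
plain `t i j` lines (gzip supported); raw second timestamps are rebinned
with `--time-unit`.

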