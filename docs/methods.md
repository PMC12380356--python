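# Methods

## Data model and time conventions

A temporal network is a node set plus a deduplicated stream of undirected
contact events (u, v, t) on integer snapshot indices over an inclusive
window [t_start, t_end]. One snapshot nominally spans 20 s of recording, but
nothing depends on the physical unit. Raw contact lists (`t i j` per line)
are rebinned as (t − t_min) // time_unit; duplicate triples collapse because
the activity indicator is binary. Node identifiers are opaque strings; the
lexicographic order canonicalizes pairs and breaks every tie downstream, so
all outputs are bit-reproducible for a given input and seed.

Two readings of "temporal degree" coexist in the literature the measures
come from: the number of *distinct* neighbours contacted in a window versus
the raw *contact count* (sum of the indicator). Both are exposed via a mode
flag; `distinct_neighbors` is the default everywhere because the semi-local
measures reason about neighbour sets. The two coincide on single-snapshot
windows.

## Time-respecting paths

Paths use strict time increase: the source may depart on any event at
t ≥ t0, and every relay hop must occur strictly after the relaying node was
reached — no multi-hop spread within one snapshot. Temporal distance is
arrival minus departure (0 for a direct contact in the departure snapshot,
∞ when unreachable). Consequence worth noting: distances do not satisfy the
naive triangle inequality; the sound composition is
τ(u,w,t0) ≤ τ(u,v,t0) + 1 + τ(v,w, arrival+1), because the continuation must
leave one snapshot after the arrival. The test suite asserts this form.

Shortest-path counting builds the DAG of optimal final hops during the
earliest-arrival sweep and counts path multiplicities forward and suffix
counts backward; temporal betweenness accumulates Brandes-style dependencies
over that DAG, summed over ordered pairs for one global departure time
(the start of the window — the convention is recorded in the scores'
`params`). Temporal closeness is harmonic (1/∞ = 0) with a one-step floor
for direct contacts, τ′ = max(τ, 1), so reciprocals are always defined.

## Temporal base cycles

Base cycles are one non-tree (chord) edge plus the tree path between its
endpoints, over an earliest-arrival spanning tree from a root (default: the
smallest node of each aggregate component; the cycle set is root-dependent,
which is inherent to base-cycle constructions). A chord is temporally
admissible when it has an activation no earlier than both endpoints' arrival
times, and the cycle's formation time is the latest constituent event —
cycles "complete" over time, and `cycles_at_time(t)` returns those completed
by t.

The cycle flow deliberately uses *weak* time ordering (≥, with fixed-point
closure inside each snapshot), unlike paths: a flow reaching one node of a
snapshot's contact subgraph is taken to traverse that subgraph within the
snapshot. This is what makes a network whose events all share one snapshot
behave exactly like its static aggregate — the base-cycle count then equals
the cyclomatic number E − N + C, which the tests verify against networkx's
static cycle basis — while spread-out activations still produce genuinely
temporal, time-resolved cycle sets. Under strict ordering no such
correspondence is possible (a strict tree cannot even span a one-snapshot
component), and on the worked example both orderings give identical cycles.

## The measures

**TSCR.** From the cycle co-membership matrix AC (diagonal = per-node cycle
counts), TSCR(i) sums AC_ij/AC_jj over co-members, including the node's own
unit term. Two aggregations exist: `final_matrix` (default) evaluates the
full-horizon matrix once; `cumulative_sum` re-evaluates on each snapshot's
completed-cycle matrix and averages over snapshots with at least one cycle,
so its scale matches the final-matrix mode and the two coincide when all
cycles complete immediately. The chosen mode is recorded in
`CentralityScores.params`.

**TSLI.** I(i) = d_i + Σ_{j∈Γ(i)} λ(e)·|d_i + d_j − 2w(i,j)|·w(i,j)·d_i/(d_i+d_j),
with w(i,j) the edge's total active time and λ(e) = P(e)+1 its cycle factor.
The absolute value is taken because well-cycled, long-active edges otherwise
drive the bracket negative. Note the measure is *not* bounded by twice the
degree: w enters multiplicatively, so long-active edges dominate.

**TSLC.** Counts distinct second-order in-neighbours under forward time
order; the membership condition reduces to "first activation of (i,i′)
strictly before last activation of (i′,j)", which is how it is implemented.

**Baselines.** TDD is the mean squared gap between snapshot degree and
static degree over the window (no square root, matching the definition this
package follows). SCL counts 2-walks on the static aggregate (row sums of
A²). TB and TC are described above.

## SIR engine and experiments

Synchronous per-snapshot updates: transmissions are evaluated on the states
at the start of the snapshot (each susceptible-infectious contact fires
independently with probability β), recoveries (probability γ) are applied
after transmission, newly infected nodes become infectious from the next
snapshot, and recovery is absorbing. The update order is a documented choice;
evaluating recoveries first would slightly lower transmission. With β = 1
and γ = 0 a run's final infected set equals the temporal reachable set of
the seed, which serves as an exact oracle in the tests, as does the binomial
law on a two-node network.

Ω(t) averages newly-infected counts over M independent runs whose generators
are spawned from one seed sequence, so every experiment is reproducible from
a single integer. The isolation experiment removes the top-ranked fraction
(ties broken canonically, ceil(fN) nodes), draws one uniform seed per run
among survivors, and reports the mean per-run peak with a 95% normal
approximation CI (mean ± 1.96·SE) — the CI convention is a choice, recorded
here. The seeding experiment seeds the top fraction and forces β = 1 for
that experiment only.

Robustness removes top-ranked fractions and reports the largest connected
component of the static aggregate (node count); a temporal-reachability
variant sits behind a flag, aggregate connectivity being the standard
percolation readout. Correlations are Pearson r with two-sided p-values from
the t-transform; a constant score vector has no defined correlation and is
exported as the marker `U`.

## Synthetic generators

`snapshot_er` draws each snapshot as an independent G(n, p) — memoryless,
homogeneous contacts, useful for invariant checks but without the burstiness
or community structure of real proximity data. `activity_driven` gives nodes
heavy-tailed activity rates with small per-snapshot star emissions,
reproducing heterogeneous temporal degrees but still no long-range temporal
correlation. `planted_cycles` embeds node-disjoint, temporally admissible
triangles (path laid down in time order, chord strictly later) in sparse
noise and returns the planted node sets, giving cycle enumeration a known
ground truth. Passing tests on these generators therefore validates the
*mechanics* of the measures and experiments, not their epidemiological
performance on real contact data, which has structure the generators do not
emulate.

Default experiment settings are β = 0.5, γ = 0.005 and M = 100 runs — the
conditions used for the evaluation experiments on empirical data. The test
and acceptance runs use small synthetic instances (tens of nodes, ≤ 50
snapshots, 50–200 Monte-Carlo instances), which the package treats as its
reference problem sizes for verification.

## The worked example and its calibration

The ten-node example (V0..V9) is reconstructed from its published summary:
the 15-edge topology follows from the printed six-cycle set, but the edge
*activation times* are figure-only information not recoverable from text.
The bundled time assignment (`data/worked_example_times_synthetic.json`) is
a synthetic reconstruction found by constrained search so that the network
reproduces every text-derivable property: the six base cycles from V0, the
four-cycle subset completed by t = 5, TSLC(V7) = 6 with second-order set
{V0, V1, V2, V5, V6, V8}, TSLC(V6) = 5, V6 as temporal-degree argmax,
TSLI ranking V7 first and V6 second, and V7 carrying the longest-active
edges. Swap in a different JSON to use other labels.

Known residuals, stated plainly:

* The published TSCR values for this example (e.g. 6.11 for V6) cannot be
  derived from the cycle-ratio formula on the printed cycle list under any
  cumulative time-weighting — an exhaustive check over all formation orders
  and convex snapshot weightings leaves a best-case deviation of ≈ 0.17.
  The package reports the exact matrix evaluation (V6 = 6.00, V2 = 5.9167,
  V0 = 4.00); the published ordering (V6 before V2) is reproduced exactly.
* The published TSLI values are likewise unreachable from the stated
  formula: TSLI(V5) = 2 would require both of V5's edge terms to vanish,
  which is impossible for integer active times, and the formula's minimum
  for V6 exceeds the published value several-fold. The package computes the
  formula faithfully and preserves the published ranking (V7 > V6 > rest).
* The published per-node TSLC row is not jointly satisfiable with the
  published V7 second-order set — two inequality chains over first/last
  activation times close into strict cycles — so the fixture matches the
  published counts for eight of ten nodes and deviates on V4 and V9.

## Limitations

Single undirected event streams only: no inter-event durations, directed or
weighted contacts, waiting-time-limited paths, or memory/expiration models.
Base-cycle sets depend on the root and tree, as in all cycle-basis
constructions. Temporal betweenness uses one global departure time rather
than averaging over departures, and exact counting limits it to moderate
networks. The SIR engine is discrete-time and synchronous, not a
continuous-time (Gillespie) simulation.
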