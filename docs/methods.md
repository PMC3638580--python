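# Methods

## Model

A signalling pathway is modelled as a directed graph whose nodes are
proteins, small molecules, or terminal events, and whose arrows point
downstream. Signal transmission cost is an edge weight; the unperturbed
network is uniform at 10 (an arbitrary but fixed baseline — only ratios of
efficiencies matter). Inhibiting a protein makes its outgoing edges costly:
for docking score `s` against target `T` with reference score `s_ref > 0`,
all edges leaving `T` get

    EV = clamp(10^(c · s / s_ref), floor, cap),  c = 2.30, floor = 10, cap = 99999.

The reassignment *replaces* the baseline weight (it does not multiply it),
and edges not leaving a profiled target stay at the initial weight. The
constant is exactly 2.30, not ln 10; the reference-ligand edge value is
therefore 10^2.30 = 199.526…, conventionally quoted as 200. Scores at or
below `s_ref · log10(floor)/c ≈ 0.4348 · s_ref` (including all negative and
missing scores, which are treated as 0 and logged) clamp to the floor and
leave the network untouched. The cap is the fully-blocked edge value; it
also keeps weights finite for scores far above the reference.

Damage is measured by weighted shortest-path statistics (Dijkstra, positive
weights required):

* network efficiency `NE = Σ_{i≠j} 1/d_ij` over ordered node pairs,
  `1/∞ = 0` for unreachable pairs;
* network flux `NF = Σ_{i≠j, j∈exits} 1/d_ij`, the restriction of NE to
  destinations in the exit set — damage near the pathway's terminal event
  counts for more. NF ≤ NE by construction.

Raising any edge weight can only lengthen shortest paths, so both
statistics are non-increasing under attack; the property suite checks this,
and checks both sums against an independent Floyd–Warshall oracle.

Per compound, NE and NF of the reweighted network are expressed as
percentages of the compound-free baseline (`relative`) and as their
complements (`decrease`); the headline efficacy predictor is the geometric
mean `√(NE_dec · NF_dec)`. Negative decreases (efficiency rising, possible
only through numerical noise here) are clamped to zero inside the geometric
mean only and reported raw elsewhere.

## Design choices

* **Directedness and pair mode.** Arrows are directional, so NE sums over
  ordered pairs by default. An `unordered` mode is provided (one term per
  pair `{i, j}` using the shorter direction) because the efficiency sum is
  sometimes stated over N(N−1)/2 pairs; the ordered mode is the default and
  the one used everywhere in the package.
* **Exit set.** Exits default to the sinks (out-degree 0). A network with
  no sink and no explicit `%exit` declaration is a configuration error
  rather than a silent guess. The curated platelet network declares its
  single terminal aggregation event explicitly.
* **Strict id matching.** Node, target and compound ids match exactly and
  case-sensitively across files; a profiled target absent from the network,
  or a compound absent from the activity table, is an error, not a warning —
  silent drops would bias NE/NF and the correlations.
* **Correlation.** "Correlation" is Pearson's product-moment r together
  with the least-squares slope and intercept (not r²). At least 3 points
  and nonzero variance are required.
* **Ranking.** Stable descending sort on the chosen key with lexicographic
  compound-id tie-breaking, so reports are reproducible byte for byte.

## Bundled fixtures

* `targets_table1.csv` — the 19 docking targets of the platelet cascade
  with their reference-ligand docking scores (e.g. thrombin 5.02,
  adenylate cyclase 6.38).
* `table2_compounds.csv` — 21 assayed compounds: fractional inhibition of
  ADP-induced whole-blood platelet aggregation at 34 µM, NE/NF percentage
  decreases, the published combination score, and glycoside (7) and
  approved-drug (2) flags. 14 of the 21 published combination cells differ
  from `√(NE_dec · NF_dec)` by more than 0.15 (plausibly computed from
  unrounded internal values); the loader therefore adds a
  `combination_recomputed` column, and formula-level checks use only the
  self-consistent rows. Correlations use the published column, which is
  what the activity data were originally compared against.
* `platelet_network.tsv` — a curated 64-node/91-edge directed
  platelet-aggregation network (19 docking targets, agonists and second
  messengers, one terminal aggregation event). It is a synthetic curation
  assembled from public pathway knowledge under the 64/91 count
  constraint; its node/edge counts and average degree (2.84) are curation
  constraints, but its exact wiring — and hence its absolute baseline NE —
  is approximate, and no test asserts a particular baseline efficiency for
  it.

## Synthetic generators

`generate_network` emulates the statistical shape of a curated pathway: a
DAG with `receptor_count` source receptors, `exit_count` terminal sinks,
and heavy-tailed out-degrees. Construction is a backbone path
R1 → N1 → … → Nk → X1 (guaranteeing every node sits on a receptor→exit
path), one out-link per extra receptor and in-link per extra exit, then
extra forward edges whose source is drawn with probability ∝ out-degree +
`attachment_bias` — preferential attachment on a reachability scaffold,
since raw preferential attachment does not guarantee receptor→exit
reachability. Defaults (64 nodes, 91 edges, 6 receptors, 1 exit) mirror
the curated network's scale. Acyclicity is a convenience of the
construction, not a requirement of the metrics, which handle cycles.

`generate_scores` builds a compound × target docking matrix: a planted
compound scores `potency · reference + N(0, score_noise_sd)` on its
targets, all other cells are pure noise, floored at 0. The default noise
s.d. of 0.25 score units is a realistic rescoring scatter for a scoring
function whose reference values sit around 4–9; reference scores are drawn
from the bundled 19-target table. Both generators are pure functions of
their config and seed.

What the generators do *not* emulate: correlated binding across related
targets (e.g. the two thromboxane-receptor isoforms), systematic docking
bias against flexible (glycoside) compounds, and any relation between a
target's network position and its docking tractability. Passing the
planted-potency recovery test (mean Kendall τ ≥ 0.8 over 20 seeds,
noise-free) therefore shows the pipeline is faithful, not that docking
scores of real libraries are this well behaved.

## Problem sizes and numerics

Oracle-equivalence and monotonicity properties are exercised on seeded
random digraphs of ≤ 12 nodes (100 draws), rank recovery on 24-node/40-edge
networks over 20 seeds, and the correlation ladder on the bundled
21-compound table; the whole suite completes in a few seconds. Path
lengths are summed in double precision; oracle agreement is asserted to
1e−9 and monotonicity to 1e−12. Shortest-path ties are irrelevant because
only lengths enter the sums.

## Known limitations

* The per-compound NE/NF decreases of the bundled activity table cannot be
  recomputed here: they derive from an unpublished 413 × 19 docking-score
  matrix. The table is used as a fixture for the ranking/correlation layer,
  and end-to-end behaviour is validated on synthetic planted matrices
  instead.
* The Pearson r of the NE decrease against inhibition over all 21 bundled
  rows computes to 0.694 from the published (1-dp rounded) columns; the
  originally reported 0.67 evidently used unrounded internals, and the
  corresponding check documents the discrepancy rather than papering over
  it.
* The curated network is one plausible wiring consistent with the published
  counts; efficiency values on it should be read comparatively (compound vs
  compound), not as absolute reproductions.
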