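# Methods

`connectomorph` asks how far a binary brain-like network is shaped by an
optimal trade-off between wiring cost and communication efficiency, with
segregated processing included as a third pressure. It evolves populations
of synthetic networks toward the Pareto front of each trade-off model and
runs the comparison battery (recovery, topology, robustness, morphospace,
behavior) against empirical networks or pseudo-empirical stand-ins.

## Trade-off models

A network over N regions with centroid coordinates is scored by two
objectives, both minimized:

- cost `F_c = Σ_{(i,j) connected} d_ij` — the summed Euclidean centroid
  distance over connected pairs, in mm; a proxy for axonal material cost.
- efficiency `F_e`, one of
  - `dual`: `1 − Eg`
  - `tri_eloc`: `w_Eloc (1 − Eg) + (1 − w_Eloc)(1 − Eloc)`, `w_Eloc = 0.9`
  - `tri_q`: `w_Q (1 − Eg) + (1 − w_Q)(1 − Q)`, `w_Q = 0.8`

`Eg` is Latora–Marchiori global efficiency (mean inverse shortest-path
length over ordered pairs; unreachable pairs contribute 0), `Eloc` the mean
over nodes of the efficiency of the neighbor-induced subgraph, and `Q` the
Newman–Girvan modularity of the best Louvain partition. The weights put
most pressure on integration with a segregation correction; both are
configurable in `TradeoffModelSpec`. The efficiency index `1 − F_e` and
`F_c` span each model's morphospace; the slope `(1 − F_e)/F_c` summarizes a
network's relative trade-off.

Inside the evolutionary loop `Q` is the best of 5 seeded Louvain restarts
(a cheap but stable estimate at ~1e5 evaluations per run); all reported
metrics use the full default of 100 restarts. Degenerate edgeless genomes
are legal during evolution and score the worst efficiency (`F_e = 1`)
rather than erroring, so the optimizer loop is robust.

## The evolutionary engine

A customized NSGA-II over genomes that are the upper-triangle bit vectors
of the adjacency matrix:

1. initialization: each entry Bernoulli(0.1), population 200 (scaled runs
   use 100);
2. reproduction: parents are drawn by crowded binary tournament (the
   canonical NSGA-II mating rule: lower front rank wins, ties broken by
   higher crowding distance) and paired; uniform crossover exchanges each
   entry between the two parents with probability 0.5, yielding one
   offspring per parent; uniform random disjoint pairing is available via
   configuration;
3. mutation: copies of the offspring with each entry flipped independently
   with probability 0.1 join the offspring pool;
4. selection: the 3P-candidate union (parents + offspring + mutants) is
   reduced to P by fast non-dominated sorting, ties within the last front
   broken by descending crowding distance (boundary solutions infinite;
   exact crowding ties broken by index, so selection is deterministic);
5. termination: stop at 2,000 generations, or when for 20 consecutive
   generations either the genome-multiset turnover between successive
   populations is below 5% or both objective means change by less than
   0.1% relative.

Each of the 30 independent runs (3 in scaled studies) gets a sub-seed
derived from the master seed with the run index mixed in; archives are the
non-dominated set of each final population, merged across runs with genome
deduplication and a final non-dominated filter. Fixed seeds give
bit-identical archives.

Design choices where the procedure was genuinely open: crossover is
per-entry uniform (the "swap a portion of entries" operator fixes neither
the portion nor its distribution); mutation acts on copies of the crossover
offspring, not the parents; population turnover is measured on genome
multisets; mating uses the crowded tournament of canonical NSGA-II, which
keeps selection pressure on the sparse (cheap) boundary of the front and on
weakly weighted objective terms within a limited generation budget. All are
configurable.

## Comparison statistics

- Recovery rate: over the off-diagonal upper triangle, `R1` is the fraction
  of empirical edges present in the synthetic network and `R0` the fraction
  of empirical non-edges absent. The combined `R = sqrt(R0 · R1)`
  (geometric mean) by default; the raw product is available. The geometric
  mean is adopted because degree-preserving random benchmarks at density
  ~0.1 score `R ≈ 0.41` under it, matching the benchmark regime the
  statistic is calibrated against, while the raw product gives ≈ 0.18.
- Distance-binned recovery uses 20 mm bins over 0–120 mm (left-closed,
  last bin closed); bins lacking empirical edges or non-edges are missing,
  not zero. The mid/long-range AUC integrates per-bin `R` by the trapezoid
  rule over bin midpoints at and above the 40 mm bins (midpoints 50–110 mm).
- Cost filtering keeps archive members whose `F_c` lies in the empirical
  cost range, endpoints inclusive.
- Topological dissimilarity z-scores each of the nine metrics over the
  pooled synthetic + empirical set (zero-spread metrics are excluded and
  flagged) and measures each synthetic network's Euclidean distance to the
  mean normalized empirical vector.

## Graph metrics and null models

Cp is Watts–Strogatz clustering (degree < 2 contributes 0); Lp averages
shortest paths over reachable ordered pairs only (keeping it finite on
near-connected graphs; an error mode exists); gamma and lambda normalize
Cp and Lp by the means of a degree-preserving Maslov–Sneppen null ensemble
(default 100 nulls, 10 attempted double-edge swaps per edge), and
`sigma = gamma / lambda`. Louvain community detection runs through igraph's
C implementation under a dedicated seeded RNG; Q is recomputed from the
returned partition with our own Newman–Girvan formula, and ties between
equal-Q restarts keep the first found.

Partition agreement aligns module labels by greedy one-to-one
maximum-overlap matching on the contingency table before computing Cohen's
kappa (unmatched modules get fresh labels). Hubs are the top
`floor(0.2 N)` nodes by degree, ties broken by node index. Attack curves
remove `round(f·N)` nodes at each fraction f ∈ {0.1, …, 0.9} — uniformly at
random (averaged over 100 repetitions, SD recorded) or in descending
initial-degree order (an adaptive recomputed-degree mode exists) — and
report the raw preserved Eg/Eloc on the remaining induced subgraph plus the
trapezoidal AUC over the fraction axis. Raw (not baseline-normalized)
values are reported; a normalized reading can be derived from the intact
network's metrics.

## Behavioral association

Networks map to `(F_c, 1 − F_e, slope)` morphospace points. Age
trajectories are ordinary least squares on `[1, age, age²]`; an inverted-U
is a negative quadratic coefficient. The sex contrast residualizes the
index on age and age² (linear-only available) and takes the male − female
difference of residual means. Significance is by permutation (default
10,000 shuffles of the behavioral labels), one-sided per the
"null ≥ observed" rule with an add-one correction so p is never 0; a
two-sided absolute-value mode is explicit in the result. Null statistics
are computed vectorized over all permutations.

## The synthetic cohort generator

The generator emulates the statistical structure of a diffusion-MRI cohort
on a 90-region bilateral parcellation, not its anatomy:

- Geometry: regions come in mirrored left/right pairs inside an ellipsoid
  of semi-axes (26, 46, 35) mm; the five bilateral modules sit on a ring in
  the y–z plane just off the midline (offset 8 mm), with regions scattered
  14 mm SD around their module centers. All pairwise distances are positive
  and bounded by 92 mm. The frame and scatter are set so the mean
  connected-edge length is ~0.6 of the all-pair mean distance, the regime
  of real parcellations; tighter modules make cohort networks artificially
  cheap relative to any spatially unstructured network of equal density.
- Edge weights: `w_ij = exp(−d_ij / 30 mm) · 4^[same module] ·
  2^[hub endpoint]`, with 10% of regions designated hubs — exponential
  distance decay plus modular and hub enrichment.
- Consistency: a cohort-level backbone edge set is drawn once from the
  weight field calibrated to density 0.105; each subject expresses backbone
  edges with reliability 0.9 and idiosyncratic edges drawn from the same
  field, jointly calibrated so expected subject density is 0.11. The
  backbone is what survives the "> 50% of subjects" group rule: without a
  consistent core, a flat Bernoulli field at density ~0.1 leaves the
  group network at roughly half the empirical density no matter how the
  geometry is arranged, because the mean within-module edge probability is
  capped near `target_density / within-pair-fraction ≈ 0.5`. The
  hierarchical form mirrors how real cohorts pass the group threshold:
  a reproducible core plus thin idiosyncratic connections.
- Behavior: ages are uniform over 18–88; subject density is scaled by an
  inverted-U age multiplier (peak-to-edge contrast 0.6, normalized to
  mean 1) so cost and efficiency acquire quadratic age trajectories and the
  cohort's wiring-cost range spans roughly ±25% of its center, matching the
  relative spread of individual empirical cost ranges; males get a 3%
  relative density boost; the fluid-intelligence-like score is
  `44 − 0.25·age + N(0, 5.75²)`, giving an age–score correlation ≈ −0.6.

At these defaults the group network lands at density ≈ 0.10–0.11 with
Louvain Q ≈ 0.55–0.62 and the planted five modules recovered essentially
perfectly — the regime of group-level human connectomes. What the generator
does *not* emulate: realistic anatomy or tract geometry, heavy-tailed
degree distributions beyond the hub boost, inter-subject geometric
variability (all subjects share one geometry), and any genuine
brain–behavior coupling beyond the planted density effects. Tests passing
on these cohorts therefore validate the machinery and its calibration, not
claims about real brains.

## Scaled-down study sizes

The end-to-end study (`connectomorph.study.run_small_world_study`, also the
reproduction script) uses 60 regions, population 100, at most 300
generations, 3 runs per model, a cost window equal to the synthetic
cohort's full subject-level cost range — the same restriction the
full-scale analysis applies to its empirical cohort — and 20 nulls per
network for sigma. At desk scale the evolved fronts reach down into the
upper part of that range; restricting to an interior sub-window would need
the full-scale exploration budget (2,000 generations, 30 runs) to populate. These sizes keep a full three-model study around a quarter hour on a
single CPU while preserving the qualitative regime of the full-scale
configuration (90 regions, population 200, 2,000 generations, 30 runs,
100 nulls), which the same code runs by changing the configuration objects.

## Numerical notes and limitations

- Shortest paths are computed by JIT-compiled all-pairs BFS on dense
  adjacency matrices — exact, and fastest in the N ≤ 90 regime the package
  targets; it is not meant for large sparse graphs.
- Louvain is a stochastic heuristic: reported Q is a lower bound on the
  optimal modularity. On small graphs (N ≤ 7) the restarted search matches
  exhaustive partition enumeration exactly in tests.
- Probability calibration solves `mean(min(c·w, 1)) = target` by bracketed
  root finding; it fails loudly if the target is unreachable with
  probabilities ≤ 1.
- The empirical cost interval printed for cost filtering in the source
  study (15,958–27,544 mm) is accepted as an optional configuration value;
  it is a wiring-cost (F_c) range.
- Attack curves at fraction 0.9 can leave fewer than 2 nodes; Eg and Eloc
  are defined as 0 there.
- With an odd population size the leftover parent is paired with a
  uniformly drawn partner; default populations are even.
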