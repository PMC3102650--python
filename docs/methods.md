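# Methods

`surrosel` evaluates how well *indicator groups* — subsets of a
regional species pool — act as surrogates for whole-assemblage
representation in complementarity-based reserve selection, and whether
a group's performance is *consistent* across two regions. This note
records the models, the numerical choices, and what the synthetic data
do and do not establish.

## The evaluation design

The analysis runs on a boolean species × grid-cell presence/absence
matrix per region plus per-species metadata (taxonomic order,
threatened flag, endemic flag). Nine candidate indicator groups are
built per region: one group per taxonomic order with at least 17
species, a pooled group of the remaining ("species-poor") orders,
threatened species, endemic species, and restricted-range species —
the 10% of species with the fewest occupied cells, including every
species tied with the cutoff occupancy (the tie rule makes the group
invariant to row order and explains counts slightly above 10%).

Evaluation is two-staged:

1. **Minimum set coverage.** For each group (and for all species
   pooled), find the smallest cell set in which every member occurs in
   at least `goal` cells (default 3, a pragmatic persistence proxy).
   Targets are capped at each species' occupancy — a species occupying
   two cells gets a target of two — so every instance is feasible. The
   region's **site budget** is the smallest minimum-set size over the
   nine groups: comparing groups at a common, data-derived budget
   removes the bias a group would gain just by needing more sites.
2. **Maximal representation.** For each group, 20 independently seeded
   solutions maximize the number of member species represented within
   the budget. Two reference models bracket the comparison: a **null
   model** (each run optimizes a freshly drawn random species set
   whose size is the rounded mean indicator-group size) and an
   **ideal model** (optimizing all species at once). Every solution is
   scored as the percentage of *target* species represented in at
   least `eval_threshold` selected cells (default 1); the target is
   all species except the tested indicator's own members, and each
   indicator group in turn minus any shared species. Removing shared
   species avoids inflating a group's apparent effectiveness with its
   own members; the null and ideal models are scored against targets
   whole, since they have no fixed membership. The optimization stage
   uses the same representation threshold the score uses — optimizing
   a 3-occurrence criterion while scoring single-occurrence presence
   would reward range-overlap clustering the score never sees.

The long-format evaluation table (region, group, run, target,
representation %) feeds a fixed-effects two-way ANOVA (region × group
with interaction) on the "all" target. Besides the factorial
decomposition, the overall model F over the region × group cell means
is reported with df (cells − 1, N − cells): with 11 evaluation groups,
2 regions and 20 runs, (21, 418). All pairwise cell contrasts use
Tukey's HSD, `q = |m_i − m_j| / sqrt(MS_resid / n)`, with p-values
from the studentized-range distribution (k = number of cells). The
significance level defaults to 1% — deliberately conservative because
replicate solutions reuse many of the same cells and are therefore not
fully independent. A group is **effective** in a region when its mean
representation exceeds the same-region null model's *and* the contrast
is significant; it is **consistent** when its two regional means are
*not* significantly different. Percentages are analysed untransformed.

## Solvers

Both problems are solved by simulated annealing over cell subsets,
with a deterministic greedy heuristic as baseline and an exhaustive
enumeration oracle (≤ 20 cells) for testing.

*Minimum set.* State: any cell subset; cost
`|selection| + spf · Σ_s max(0, target_s − representation_s)` with the
species penalty factor defaulting to 10 × n_cells so any shortfall
outweighs any site saving. Moves toggle one uniformly random cell;
worse states are accepted with probability `exp(−Δ/T)`. The best-ever
state is returned after (a) a greedy repair pass if any target is
unmet — the feasibility contract holds unconditionally — and (b) an
iterative-improvement pass that removes redundant cells (in increasing
id order, to a fixed point), the customary final polish in
site-selection tools. If the greedy solution is smaller, it is
returned instead; this also makes the dominance chain
`exhaustive ≤ annealed ≤ greedy` hold on every instance.

*Maximal coverage.* State: a subset of exactly `budget` cells; a move
swaps one selected for one unselected cell; the objective is the
number of in-scope species meeting their targets. Ties in that count
are broken lexicographically toward selections with more total
in-scope presences (ε-weighted with ε < 1/(1 + total presences), so
the primary objective is never traded). Coverage plateaus are wide —
many selections cover equally many species — and without the tie-break
each run returns an arbitrary plateau point, inflating run-to-run
variance in the downstream ANOVA without changing its mean structure.

*Schedule.* Defaults: 100,000 iterations per restart, 10 restarts,
geometric cooling ×0.95 applied every iterations/100 steps, initial
temperature "auto" = the standard deviation of the objective deltas of
100 random candidate moves from the initial state (1.0 if degenerate).
The pipeline uses lighter schedules suited to its instance sizes —
15,000 iterations × 1 restart per coverage run (the 20 independent
runs already play the restart role) and 40,000 × 3 for the few
minimum-set solves. Everything is exposed via `AnnealSchedule`.
Tie-breaks elsewhere (greedy, oracle, pruning) use the lowest cell id;
identical (problem, schedule, seed) triples reproduce solutions
exactly, and the whole pipeline is a pure function of one master seed.

## The synthetic generator

Real analyses of this kind clip extent-of-occurrence range maps onto a
half-degree grid; no such data ship with this package, so a generator
produces paired regions with the structure the method assumes:

- **Grid**: an abstract row-major lattice with rook adjacency; two
  regions of unequal size share one taxonomic order list.
- **Occupancy**: each species' occupied fraction is log-normal
  (default μ = log 0.12, σ = 1.4, truncated to [1 cell, all cells]).
  The right skew makes the bottom-decile "restricted range" group
  meaningful; the long right tail reflects that extent-of-occurrence
  maps let common species span large parts of a region — which is what
  allows a widespread order to be fully represented in a handful of
  cells and keeps site budgets at a few percent of the grid.
- **Range shape**: spreading dye — from a seed cell, add one uniformly
  random rook-adjacent frontier cell per step — the standard null
  model for contiguous geographic ranges.
- **Endemism** (default 12% of species): endemics are seeded inside a
  contiguous rectangular window (default 20% of the grid area), making
  their ranges spatially clumped.
- **Habitat heterogeneity**: non-endemic species occupying less than
  15% of the grid are habitat specialists, seeded at one of ~n_cells/20
  pocket cells. Pockets are stratified — one uniform draw per block of
  a lattice tiling, excluding the endemic window — and specialists are
  dealt to pockets smallest-range-first in rotation, so every pocket
  hosts its own narrow-ranged species. This encodes the ecology the
  evaluation is about: restricted-range species sit in scattered,
  distinct communities of co-occurring specialists (high beta
  diversity), so sites chosen for them are complementary; without any
  co-occurrence structure, a solution optimized for scattered rare
  species is statistically indistinguishable from a random cell set
  and no indicator group can beat the null model.
- **Threat status** (default 8% of species in expectation): drawn with
  probability logistic in centred −log occupancy (slope 2.0), so
  threat concentrates among small-ranged species; the intercept is
  solved numerically so the expected threatened fraction matches the
  config regardless of the realized occupancy spread.
- **Randomness**: one master seed; every species, the pocket layout
  and the threat draw use named spawned sub-streams, so output is
  bitwise reproducible and independent of generation order.

Two standard scales are provided: `"desk"` (360- and 255-cell regions,
222 and 220 species) and `"reduced"` (210/182 cells, 126/120 species)
for replicated simulation studies; at the reduced scale the five large
orders keep ≥ 17 species so the species-poor threshold yields the same
nine-group structure.

**What the synthetic data do not show.** The generator reproduces the
qualitative mechanism, not any real region: no real geography or
projections, no abundance, no temporal dynamics, no spatial
autocorrelation in environmental suitability beyond the pocket/window
device, and order membership carries no spatial signal — so taxonomic
groups behave like size-matched random groups here, whereas real
orders have distinctive spatial patterns. Passing tests establish that
the pipeline detects the scattered-rarity-vs-clumped-endemism contrast
when it is present, not that any particular real-world group is a good
surrogate.

## Numerical and interface choices

- Cell ids are 0-based row-major integers everywhere; geographic
  coordinates never appear.
- Planning-unit costs are fixed at 1 and there is no boundary-length
  term: the analyses optimize site counts only.
- On-disk formats are UTF-8 comma-separated: the assemblage pair
  (matrix.csv, metadata.csv) and the MARXAN input triplet
  (pu.dat/spec.dat/puvspr.dat, amount 1 per presence, rows sorted by
  planning unit then species). Loading validates ids and rejects
  zero-occupancy species, naming the offending id. The two-CSV format
  does not carry grid dimensions, so loaded assemblages have no grid;
  nothing downstream of generation needs adjacency.
- Zero-variance evaluation tables (all observations equal) short-
  circuit the ANOVA with an explicit flag and undefined (NaN) F.
- Degenerate Tukey inputs (zero residual MS) give q = ∞ / p = 0 for
  unequal means and q = 0 / p = 1 for equal ones.
- Group-building skips groups that are empty in a region (with a
  logged warning) rather than failing, so small assemblages still run
  end to end; evaluation and ANOVA then operate on the groups present.

## Problem sizes used in the shipped studies

The test suite and `scripts/acceptance.py` exercise: solver-vs-oracle
studies on 50 random instances of ≤ 12 cells and ≤ 10 species; 1,000
(tests) / 200 (script) randomized feasibility solves; one full
desk-scale analysis (20 runs per group); and 25 replicate
reduced-scale pipelines for the headline contrast. These sizes keep
each study to a few minutes while leaving the statistics
interpretable; all scale knobs are plain function arguments.

## Known limitations

- The annealing schedule is generic; no adaptive temperature control.
- The null model's species-set size rule (mean group size) and the
  per-run redraw are design choices; both are configurable.
- Consistency classification requires the same group names in both
  regions and exactly two regions.
- The brute-force oracle is exponential and refuses > 20 cells by
  design.
- With very small site budgets (a smallest-group minimum set of ≤ 3–4
  cells) the budget-constrained stage has too little room to
  discriminate between indicator groups, and effectiveness calls
  become noisy; this mirrors the method, not a solver defect.
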