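# surrosel

Indicator-group surrogacy evaluation for complementarity-based reserve
selection.

Conservation planners rarely have distribution data for everything, so
site prioritization leans on *indicator groups*: species subsets whose
spatial distribution is used to pick sites intended to represent the
whole assemblage. `surrosel` implements a full, reproducible
evaluation of such groups for species-by-site presence/absence data:

- build nine candidate groups per region (large taxonomic orders, the
  pooled species-poor orders, threatened, endemic, and
  restricted-range species — the bottom 10% of occupancy, ties
  included);
- solve the **minimum set coverage problem** (smallest cell set where
  every species meets a representation target, default "at least 3
  cells", capped at occupancy) and the **maximal representation
  problem** (maximize species represented within a fixed site budget)
  with simulated annealing, backed by a greedy baseline and an
  exhaustive oracle for small instances;
- run the two-region evaluation: the site budget per region is the
  smallest group's minimum set; each group gets 20 independently
  seeded budget-constrained solutions, bracketed by a **null model**
  (random species sets) and an **ideal model** (all species), each
  scored as the % of target species represented (targets exclude the
  tested group's own members);
- classify groups with a two-way ANOVA (region × group, overall model
  F on (cells−1, N−cells) df) and Tukey HSD at α = 0.01: **effective**
  = significantly above the same-region null model, **consistent** =
  not significantly different between regions.

A synthetic paired-hotspot generator (contiguous spreading-dye ranges,
right-skewed occupancy, zone-clumped endemics, scattered habitat
pockets of co-occurring specialists, occupancy-biased threat status)
makes the entire analysis runnable and testable with no external data.
The science and all numerical choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import surrosel as ss

cfg_a, cfg_b = ss.default_paired_configs("reduced")   # 2 regions, ~120 species each
res = ss.run_pipeline(cfg_a, cfg_b, seed=3, n_runs=20)
print(res.budgets)
```

This generates the paired regions, derives each region's site budget,
runs 22 × 20 annealed coverage solutions, and performs the ANOVA/Tukey
classification (about a minute). Output from
`python examples/04_evaluate_surrogacy.py`, abridged:

```
site budgets (smallest group minimum set): {'region_a': 7, 'region_b': 12}

mean +/- SD representation of all target species over 20 runs:
                              mean  std
region_a endemic              38.4  3.1
         ideal                93.9  0.8
         null                 76.5  5.8
         restricted_range     89.7  1.8
...
overall model F_21,418 = 292.01 (p = 1.1e-234)

consistency (no significant difference between regions):
              group  p_between_regions  consistent
            endemic              0.000       False
   restricted_range              0.243        True
```

Reading it: within a 7-cell budget in region A, sites optimized for
the restricted-range group represent 89.7% of all other species —
close to the ideal model (93.9%) and far above the null model (76.5%)
— while sites optimized for the clumped endemic group capture only
38.4%. Here the restricted-range group is the only one classified
effective in both regions *and* consistent across them: scattered
small-ranged species sample a region's habitat heterogeneity, clumped
endemics do not.

The `examples/` directory holds one short script per capability:
simulation and CSV export, group construction, the three solvers plus
MARXAN-dialect export, the full evaluation, and report rendering
(tables, bar-chart data with error bars, figures).

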