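"""Two-stage surrogacy evaluation pipeline.

Stage 1 (per region): the smallest site set representing each indicator
group's own species at the representation goal — the "sites required"
table. The minimum over indicator groups becomes the region's site
budget, so group effectiveness can be compared without bias from the
number of sites each group happens to need.

Stage 2 (per region): for every indicator group, ``n_runs``
independently seeded budget-constrained coverage solutions for the
group's members; a null model (a fresh random species set per run) and
an ideal model (all species) bracket the comparison from below and
above. Every solution is scored as the percentage of target species it
represents — the target being all species minus the indicator's own
members, and each indicator group in turn (minus shared species).

The resulting long-format evaluation table feeds the two-way ANOVA and
Tukey classification in :mod:`surrosel.stats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assemblage import Assemblage, PresenceAbsence
from .groups import GroupSet, build_all_groups
from .solvers import (
    MAX_COVERAGE,
    MIN_SET,
    AnnealSchedule,
    ProblemSpec,
    Solution,
    anneal,
    capped_targets,
)

__all__ = [
    "ALL_SPECIES_ROW",
    "NULL_MODEL",
    "IDEAL_MODEL",
    "TARGET_ALL",
    "MAXCOV_SCHEDULE",
    "MINSET_SCHEDULE",
    "minimum_sites_table",
    "budget_from_smallest_group",
    "representation_pct",
    "evaluate_region",
    "evaluate_paired",
    "PipelineResult",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

ALL_SPECIES_ROW = "All species"
NULL_MODEL = "null"
IDEAL_MODEL = "ideal"
TARGET_ALL = "all"

#: Default schedule for the per-run coverage solves; the 20 independent
#: seeded runs already play the restart role.
MAXCOV_SCHEDULE = AnnealSchedule(iterations=15_000, restarts=1)
#: Default schedule for the minimum-set stage (few solves, sizes matter).
MINSET_SCHEDULE = AnnealSchedule(iterations=40_000, restarts=3)


def minimum_sites_table(
    assemblage: Assemblage,
    groups: GroupSet,
    goal: int = 3,
    schedule: AnnealSchedule = MINSET_SCHEDULE,
    rng=None,
) -> pd.DataFrame:
    """Minimum-set size per indicator group and for all species pooled.

    Returns one row per group plus an ``"All species"`` row, with the
    group's species count and the annealed minimum number of sites
    meeting the (occupancy-capped) representation goal.
    """
    if goal < 1:
        raise ValueError("goal must be >= 1")
    gen = np.random.default_rng(rng)
    matrix = assemblage.matrix
    rows = []
    scopes = [(g.name, sorted(g.members)) for g in groups]
    scopes.append((ALL_SPECIES_ROW, list(matrix.species)))
    for name, members in scopes:
        sub = matrix.subset_species(members)
        problem = ProblemSpec(matrix=sub, targets=capped_targets(sub, goal), mode=MIN_SET)
        sol = anneal(problem, schedule, gen)
        rows.append((assemblage.region, name, len(members), sol.n_cells))
    return pd.DataFrame(rows, columns=["region", "group", "n_species", "n_sites"])


def budget_from_smallest_group(sites_table: pd.DataFrame) -> int:
    """Site budget: the smallest group minimum-set size (all-species row excluded)."""
    rows = sites_table[sites_table["group"] != ALL_SPECIES_ROW]
    if rows.empty:
        raise ValueError("sites table has no indicator-group rows")
    return int(rows["n_sites"].min())


def representation_pct(
    solution,
    matrix: PresenceAbsence,
    target_species,
    eval_threshold: int = 1,
) -> float:
    """Percentage of target species occurring in >= threshold selected cells."""
    if eval_threshold < 1:
        raise ValueError("eval_threshold must be >= 1")
    targets = [str(s) for s in target_species]
    if not targets:
        raise ValueError("target species set is empty")
    cells = solution.cells if isinstance(solution, Solution) else list(solution)
    counts = matrix.presence_in(cells).loc[targets]
    return 100.0 * float((counts >= eval_threshold).sum()) / len(targets)


def evaluate_region(
    assemblage: Assemblage,
    groups: GroupSet,
    budget: int,
    n_runs: int = 20,
    goal: int = 3,
    eval_threshold: int = 1,
    null_set_size: int | None = None,
    schedule: AnnealSchedule = MAXCOV_SCHEDULE,
    rng=None,
) -> pd.DataFrame:
    """Stage-2 evaluation of one region.

    For each indicator group, the null model and the ideal model, runs
    ``n_runs`` independently seeded coverage solves within ``budget``
    sites and scores every solution against the "all" target and each
    indicator group as target. The coverage objective counts in-scope
    species at the same representation threshold the solutions are
    scored at (``eval_threshold``, capped at occupancy), so the solver
    maximizes exactly the measure being compared. Records where the
    target set becomes empty after removing species shared with the
    tested indicator are omitted. Returns the long-format table
    (region, group, run, target, representation_pct).
    """
    matrix = assemblage.matrix
    if not (1 <= budget <= matrix.n_cells):
        raise ValueError(f"budget must be in [1, {matrix.n_cells}], got {budget}")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if len(groups) == 0:
        raise ValueError("no indicator groups to evaluate")
    gen = np.random.default_rng(rng)
    all_species = list(matrix.species)
    cover_targets = capped_targets(matrix, eval_threshold)
    if null_set_size is None:
        null_set_size = int(round(np.mean([len(g) for g in groups])))
    null_set_size = min(max(1, null_set_size), len(all_species))
    logger.info(
        "%s: budget=%d, runs=%d, null set size=%d",
        assemblage.region, budget, n_runs, null_set_size,
    )

    group_members = {g.name: set(g.members) for g in groups}
    entities = [g.name for g in groups] + [NULL_MODEL, IDEAL_MODEL]

    records = []
    for entity in entities:
        for run in range(1, n_runs + 1):
            if entity == NULL_MODEL:
                scope = list(gen.choice(all_species, size=null_set_size, replace=False))
                indicator_members: set[str] = set()
            elif entity == IDEAL_MODEL:
                scope = all_species
                indicator_members = set()
            else:
                scope = sorted(group_members[entity])
                indicator_members = group_members[entity]
            sub = matrix.subset_species(scope)
            problem = ProblemSpec(
                matrix=sub,
                targets=cover_targets.loc[sub.species],
                mode=MAX_COVERAGE,
                budget=budget,
            )
            sol = anneal(problem, schedule, gen)

            target_sets = {TARGET_ALL: [s for s in all_species if s not in indicator_members]}
            for tname, tmembers in group_members.items():
                remaining = sorted(tmembers - indicator_members)
                if remaining:
                    target_sets[tname] = remaining
            for tname, tset in target_sets.items():
                pct = representation_pct(sol, matrix, tset, eval_threshold)
                records.append((assemblage.region, entity, run, tname, pct))
    return pd.DataFrame(
        records, columns=["region", "group", "run", "target", "representation_pct"]
    )


def evaluate_paired(
    assemblage_a: Assemblage,
    groups_a: GroupSet,
    budget_a: int,
    assemblage_b: Assemblage,
    groups_b: GroupSet,
    budget_b: int,
    rng=None,
    **kwargs,
) -> pd.DataFrame:
    """Evaluate two regions (each with its own budget) and concatenate.

    Consistency classification needs the same group names in both
    regions and distinct region labels; both are checked here.
    """
    if assemblage_a.region == assemblage_b.region:
        raise ValueError("paired evaluation requires two distinct region labels")
    if set(groups_a.names()) != set(groups_b.names()):
        raise ValueError(
            "paired evaluation requires the same group names in both regions: "
            f"{sorted(groups_a.names())} vs {sorted(groups_b.names())}"
        )
    gen = np.random.default_rng(rng)
    stream_a, stream_b = gen.spawn(2)
    tab_a = evaluate_region(assemblage_a, groups_a, budget_a, rng=stream_a, **kwargs)
    tab_b = evaluate_region(assemblage_b, groups_b, budget_b, rng=stream_b, **kwargs)
    return pd.concat([tab_a, tab_b], ignore_index=True)


@dataclass
class PipelineResult:
    """Everything one end-to-end paired analysis produces."""

    assemblages: tuple[Assemblage, Assemblage]
    group_sets: tuple[GroupSet, GroupSet]
    sites_table: pd.DataFrame
    budgets: dict[str, int]
    eval_table: pd.DataFrame
    anova: object
    tukey: object
    classification: object


def run_pipeline(
    config_a,
    config_b,
    seed,
    n_runs: int = 20,
    goal: int = 3,
    eval_threshold: int = 1,
    fraction: float = 0.10,
    poor_threshold: int = 17,
    null_set_size: int | None = None,
    alpha: float = 0.01,
    labels: tuple[str, str] = ("region_a", "region_b"),
    minset_schedule: AnnealSchedule = MINSET_SCHEDULE,
    maxcov_schedule: AnnealSchedule = MAXCOV_SCHEDULE,
) -> PipelineResult:
    """Run the whole analysis on freshly generated paired hotspots.

    Generation, both solver stages and the null draws all derive from
    one master seed, so the full result is reproducible.
    """
    from .stats import classify, tukey_hsd, two_way_anova
    from .synthetic import generate_paired_hotspots

    gen = np.random.default_rng(seed)
    gen_stream, eval_stream = gen.spawn(2)
    asm_a, asm_b = generate_paired_hotspots(config_a, config_b, gen_stream, labels)
    groups_a = build_all_groups(asm_a, fraction, poor_threshold)
    groups_b = build_all_groups(asm_b, fraction, poor_threshold)

    sites_stream_a, sites_stream_b, pair_stream = eval_stream.spawn(3)
    sites_a = minimum_sites_table(asm_a, groups_a, goal, minset_schedule, sites_stream_a)
    sites_b = minimum_sites_table(asm_b, groups_b, goal, minset_schedule, sites_stream_b)
    sites = pd.concat([sites_a, sites_b], ignore_index=True)
    budget_a = budget_from_smallest_group(sites_a)
    budget_b = budget_from_smallest_group(sites_b)

    eval_table = evaluate_paired(
        asm_a, groups_a, budget_a,
        asm_b, groups_b, budget_b,
        rng=pair_stream,
        n_runs=n_runs,
        goal=goal,
        eval_threshold=eval_threshold,
        null_set_size=null_set_size,
        schedule=maxcov_schedule,
    )
    anova = two_way_anova(eval_table, target=TARGET_ALL)
    tukey = tukey_hsd(anova, alpha=alpha)
    classification = classify(eval_table, tukey, alpha=alpha)
    return PipelineResult(
        assemblages=(asm_a, asm_b),
        group_sets=(groups_a, groups_b),
        sites_table=sites,
        budgets={asm_a.region: budget_a, asm_b.region: budget_b},
        eval_table=eval_table,
        anova=anova,
        tukey=tukey,
        classification=classification,
    )
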