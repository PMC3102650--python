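"""Complementarity-based reserve-selection solvers.

Two problems are supported over a presence/absence matrix with
per-species representation targets:

* **minimum set coverage** — find the smallest cell set meeting every
  target, minimised as a penalized cost
  ``|selection| + spf * total shortfall``;
* **maximal representation (coverage)** — given a fixed site budget,
  maximize the number of species meeting their targets.

Three routes are provided: a deterministic greedy heuristic (baseline
and upper bound), simulated annealing (the production solver), and an
exhaustive enumeration oracle for small instances (<= 20 cells) used in
testing. Targets are always capped at each species' occupancy, so every
instance is feasible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _sa
from .assemblage import PresenceAbsence

__all__ = [
    "AnnealSchedule",
    "Solution",
    "ProblemSpec",
    "capped_targets",
    "min_cover_cost",
    "greedy_min_cover",
    "anneal",
    "brute_force",
    "DEFAULT_GOAL",
]

#: Representation goal: required number of selected cells per species.
DEFAULT_GOAL = 3

MIN_SET = "min_set"
MAX_COVERAGE = "max_coverage"

_BRUTE_FORCE_MAX_CELLS = 20


@dataclass(frozen=True)
class AnnealSchedule:
    """Simulated-annealing schedule.

    ``initial_temperature="auto"`` sets T0 per restart to the standard
    deviation of the objective deltas of 100 random candidate moves
    from the initial state. ``interval=None`` updates the temperature
    every ``iterations // 100`` steps, giving a fixed total geometric
    decay whatever the run length.
    """

    iterations: int = 100_000
    initial_temperature: float | str = "auto"
    cooling: float = 0.95
    interval: int | None = None
    restarts: int = 10

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling factor must be in (0, 1)")
        if self.interval is not None and self.interval < 1:
            raise ValueError("interval must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be positive")
        if self.initial_temperature != "auto" and float(self.initial_temperature) <= 0:
            raise ValueError("initial temperature must be positive or 'auto'")

    @property
    def effective_interval(self) -> int:
        return self.interval if self.interval is not None else max(1, self.iterations // 100)

    @property
    def t0_sentinel(self) -> float:
        return -1.0 if self.initial_temperature == "auto" else float(self.initial_temperature)


@dataclass(frozen=True)
class Solution:
    """A selected cell set with bookkeeping.

    ``representation`` counts, per in-scope species, the selected cells
    where the species is present; ``feasible`` means every in-scope
    species meets its (capped) target.
    """

    cells: tuple[int, ...]
    representation: pd.Series
    objective: float
    feasible: bool
    solver: str
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_covered(self) -> int:
        """Species meeting their target (needs targets via feasibility path)."""
        return int(self.representation.attrs.get("n_covered", -1))


@dataclass(frozen=True)
class ProblemSpec:
    """A solver instance: matrix restricted to the species in scope."""

    matrix: PresenceAbsence
    targets: pd.Series
    mode: str
    budget: int | None = None
    spf: float | None = None

    def __post_init__(self):
        if self.mode not in (MIN_SET, MAX_COVERAGE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.targets.index.equals(self.matrix.species):
            raise ValueError("targets must be indexed by the matrix's species, in order")
        occ = self.matrix.occupancy()
        over = self.targets > occ
        if over.any():
            bad = self.targets.index[over][0]
            raise ValueError(
                f"target for {bad!r} exceeds its occupancy; cap targets with capped_targets()"
            )
        if (self.targets < 0).any():
            raise ValueError("targets must be non-negative")
        if self.mode == MAX_COVERAGE:
            if self.budget is None:
                raise ValueError("max_coverage requires a budget")
            if not (0 <= self.budget <= self.matrix.n_cells):
                raise ValueError(
                    f"budget must be in [0, {self.matrix.n_cells}], got {self.budget}"
                )
        if self.spf is not None and self.spf <= 0:
            raise ValueError("species penalty factor must be positive")

    @property
    def effective_spf(self) -> float:
        # default: any shortfall outweighs any site-count saving
        return self.spf if self.spf is not None else 10.0 * self.matrix.n_cells


def capped_targets(matrix: PresenceAbsence, goal: int = DEFAULT_GOAL) -> pd.Series:
    """Per-species targets ``min(goal, occupancy)``.

    The representation goal (occurrence in at least ``goal`` selected
    cells) is infeasible verbatim for species occupying fewer cells;
    capping keeps every instance feasible.
    """
    if goal < 1:
        raise ValueError(f"goal must be >= 1, got {goal}")
    occ = matrix.occupancy()
    return occ.clip(upper=goal).rename("target")


def min_cover_cost(selection, matrix: PresenceAbsence, targets: pd.Series, spf: float) -> float:
    """Penalized minimum-set cost: |selection| + spf * total shortfall."""
    cells = list(selection)
    rep = matrix.presence_in(cells)
    shortfall = (targets - rep).clip(lower=0).sum()
    return float(len(cells) + spf * shortfall)


def _solution(matrix, targets, cells, objective, solver, seed=None) -> Solution:
    cells = tuple(sorted(int(c) for c in cells))
    rep = matrix.presence_in(cells).rename("representation")
    feasible = bool((rep >= targets).all())
    rep.attrs["n_covered"] = int((rep >= targets).sum())
    return Solution(
        cells=cells,
        representation=rep,
        objective=float(objective),
        feasible=feasible,
        solver=solver,
        seed=seed,
    )


def greedy_min_cover(matrix: PresenceAbsence, targets: pd.Series) -> Solution:
    """Greedy minimum-set heuristic.

    Repeatedly adds the cell covering the largest remaining shortfall
    (ties broken by lowest cell id) until every capped target is met;
    always returns a feasible solution.
    """
    vals = matrix.values
    tgt = targets.to_numpy()
    rep = np.zeros(matrix.n_species, dtype=np.int64)
    chosen: list[int] = []
    cell_ids = matrix.cells.to_numpy()
    in_sel = np.zeros(matrix.n_cells, dtype=bool)
    while True:
        need = rep < tgt
        if not need.any():
            break
        gains = vals[need].sum(axis=0)
        gains[in_sel] = -1
        j = int(np.argmax(gains))  # argmax takes the first (lowest id) on ties
        if gains[j] <= 0:  # unreachable with capped targets; guards bad input
            raise RuntimeError("no cell reduces the remaining shortfall")
        in_sel[j] = True
        chosen.append(int(cell_ids[j]))
        rep += vals[:, j]
    return _solution(matrix, targets, chosen, len(chosen), "greedy")


def _csr(matrix: PresenceAbsence) -> tuple[np.ndarray, np.ndarray]:
    """Cell-major CSR of the incidence matrix (species indices per cell)."""
    vals = matrix.values
    indptr = np.zeros(matrix.n_cells + 1, dtype=np.int64)
    cols = []
    for c in range(matrix.n_cells):
        sp = np.flatnonzero(vals[:, c])
        cols.append(sp)
        indptr[c + 1] = indptr[c] + len(sp)
    indices = (
        np.concatenate(cols).astype(np.int64) if cols else np.zeros(0, dtype=np.int64)
    )
    return indptr, indices


def _prune_redundant(matrix: PresenceAbsence, targets: pd.Series, cells) -> list[int]:
    """Iterative improvement: drop cells whose removal keeps feasibility.

    Cells are tried in increasing id order, repeatedly, until the
    selection is irredundant; deterministic for a given input.
    """
    vals = matrix.values
    tgt = targets.to_numpy()
    id_to_pos = {int(c): j for j, c in enumerate(matrix.cells)}
    selected = sorted(int(c) for c in cells)
    rep = vals[:, [id_to_pos[c] for c in selected]].sum(axis=1)
    changed = True
    while changed:
        changed = False
        for c in list(selected):
            col = vals[:, id_to_pos[c]]
            if ((rep - col) >= tgt).all():
                rep = rep - col
                selected.remove(c)
                changed = True
    return selected


def anneal(problem: ProblemSpec, schedule: AnnealSchedule | None = None, rng=None) -> Solution:
    """Solve by simulated annealing, best-ever state across restarts.

    ``rng`` may be an integer seed or a numpy Generator; the integer
    seed actually handed to the kernels is recorded on the Solution, so
    a (problem, schedule, seed) triple reproduces the result exactly.

    For ``min_set`` the returned state is guaranteed feasible and never
    worse than the greedy baseline: the best annealed state gets a
    greedy repair pass if it misses a target, then an iterative
    redundancy-pruning pass (the usual final polish in site-selection
    tools), and is swapped for the greedy solution in the rare case the
    latter is smaller.
    """
    schedule = schedule or AnnealSchedule()
    gen = np.random.default_rng(rng)
    call_seed = int(gen.integers(0, 2**31 - schedule.restarts - 1))

    matrix = problem.matrix
    tgt = problem.targets.to_numpy().astype(np.int64)
    indptr, indices = _csr(matrix)
    interval = schedule.effective_interval
    t0 = schedule.t0_sentinel
    pos_to_id = matrix.cells.to_numpy()

    if problem.mode == MIN_SET:
        spf = problem.effective_spf
        best_cost = np.inf
        best_mask = None
        for r in range(schedule.restarts):
            mask, cost = _sa.anneal_min_set(
                indptr, indices, tgt, float(spf), matrix.n_cells, matrix.n_species,
                schedule.iterations, t0, schedule.cooling, interval, call_seed + r,
            )
            if cost < best_cost:
                best_cost = cost
                best_mask = mask
        cells = [int(pos_to_id[c]) for c in np.flatnonzero(best_mask)]
        sol = _solution(matrix, problem.targets, cells, best_cost, "anneal", call_seed)
        if not sol.feasible:
            sol = _repair_min_set(matrix, problem.targets, sol, call_seed)
        pruned = _prune_redundant(matrix, problem.targets, sol.cells)
        greedy = greedy_min_cover(matrix, problem.targets)
        if greedy.n_cells < len(pruned):
            pruned = list(greedy.cells)
        return _solution(matrix, problem.targets, pruned, len(pruned), "anneal", call_seed)

    # max_coverage
    budget = int(problem.budget)
    if budget == 0:
        return _solution(matrix, problem.targets, [], 0, "anneal", call_seed)
    if budget >= matrix.n_cells:
        cells = [int(c) for c in pos_to_id]
        rep = matrix.presence_in(cells)
        obj = int((rep >= problem.targets).sum())
        return _solution(matrix, problem.targets, cells, obj, "anneal", call_seed)
    best_cov = -1
    best_sel = None
    for r in range(schedule.restarts):
        sel, cov = _sa.anneal_max_coverage(
            indptr, indices, tgt, matrix.n_cells, matrix.n_species, budget,
            schedule.iterations, t0, schedule.cooling, interval, call_seed + r,
        )
        if cov > best_cov:
            best_cov = cov
            best_sel = sel
    cells = [int(pos_to_id[c]) for c in best_sel]
    return _solution(matrix, problem.targets, cells, best_cov, "anneal", call_seed)


def _repair_min_set(matrix, targets, sol: Solution, seed) -> Solution:
    """Greedy additions until every target is met (feasibility contract)."""
    vals = matrix.values
    tgt = targets.to_numpy()
    cell_ids = matrix.cells.to_numpy()
    id_to_pos = {int(c): j for j, c in enumerate(cell_ids)}
    in_sel = np.zeros(matrix.n_cells, dtype=bool)
    for c in sol.cells:
        in_sel[id_to_pos[c]] = True
    rep = vals[:, in_sel].sum(axis=1)
    chosen = list(sol.cells)
    while True:
        need = rep < tgt
        if not need.any():
            break
        gains = vals[need].sum(axis=0)
        gains[in_sel] = -1
        j = int(np.argmax(gains))
        in_sel[j] = True
        chosen.append(int(cell_ids[j]))
        rep += vals[:, j]
    return _solution(matrix, targets, chosen, len(chosen), "anneal+repair", seed)


def brute_force(problem: ProblemSpec) -> Solution:
    """Exhaustive enumeration oracle (refuses instances above 20 cells).

    Ties (equal size for min_set, equal coverage for max_coverage) are
    broken by the lexicographically smallest sorted id set.
    """
    matrix = problem.matrix
    n = matrix.n_cells
    if n > _BRUTE_FORCE_MAX_CELLS:
        raise ValueError(f"brute force limited to {_BRUTE_FORCE_MAX_CELLS} cells, got {n}")
    vals = matrix.values
    tgt = problem.targets.to_numpy()
    cell_ids = [int(c) for c in matrix.cells]
    # per-species bitmask over cell positions
    sp_masks = []
    for i in range(matrix.n_species):
        m = 0
        for j in range(n):
            if vals[i, j]:
                m |= 1 << j
        sp_masks.append(m)

    def ids_of(mask: int) -> tuple[int, ...]:
        return tuple(sorted(cell_ids[j] for j in range(n) if mask >> j & 1))

    if problem.mode == MIN_SET:
        best_key = None
        best_mask = 0
        for mask in range(1 << n):
            size = mask.bit_count()
            if best_key is not None and size > best_key[0]:
                continue
            if all((mask & m).bit_count() >= t for m, t in zip(sp_masks, tgt)):
                key = (size, ids_of(mask))
                if best_key is None or key < best_key:
                    best_key = key
                    best_mask = mask
        cells = ids_of(best_mask)
        return _solution(matrix, problem.targets, cells, len(cells), "brute_force")

    budget = int(problem.budget)
    best_key = None
    best_mask = 0
    for mask in range(1 << n):
        if mask.bit_count() > budget:
            continue
        covered = sum((mask & m).bit_count() >= t for m, t in zip(sp_masks, tgt))
        key = (-covered, ids_of(mask))
        if best_key is None or key < best_key:
            best_key = key
            best_mask = mask
    cells = ids_of(best_mask)
    return _solution(matrix, problem.targets, cells, -best_key[0], "brute_force")
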