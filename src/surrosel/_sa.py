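"""Numba kernels for the simulated-annealing solvers.

The incidence matrix enters as a CSR-like pair (``indptr``, ``indices``)
over cells: ``indices[indptr[c]:indptr[c+1]]`` are the (scope-local)
species indices present in cell ``c``. Representation counts and
penalty shortfalls are maintained incrementally, so one move costs
O(species per cell).

Both kernels seed numba's own RNG, so a (problem, schedule, seed)
triple yields an identical trajectory on every run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["anneal_min_set", "anneal_max_coverage"]


@njit(cache=True)
def _toggle_delta(c, sel, rep, targets, indptr, indices, spf):
    # cost delta for toggling cell c (cost = n_selected + spf * shortfall)
    cnt = 0
    if sel[c] == 0:
        for k in range(indptr[c], indptr[c + 1]):
            s = indices[k]
            if rep[s] < targets[s]:
                cnt += 1
        return 1.0 - spf * cnt
    for k in range(indptr[c], indptr[c + 1]):
        s = indices[k]
        if rep[s] <= targets[s]:
            cnt += 1
    return -1.0 + spf * cnt


@njit(cache=True)
def _apply_toggle(c, sel, rep, indptr, indices):
    if sel[c] == 0:
        sel[c] = 1
        for k in range(indptr[c], indptr[c + 1]):
            rep[indices[k]] += 1
    else:
        sel[c] = 0
        for k in range(indptr[c], indptr[c + 1]):
            rep[indices[k]] -= 1


@njit(cache=True)
def anneal_min_set(indptr, indices, targets, spf, n_cells, n_species,
                   iterations, t0, cooling, interval, seed):
    """One annealing restart for the minimum-set problem.

    Starts from a uniformly random subset; moves toggle one random
    cell; worse states accepted with probability exp(-delta/T); the
    best-ever state by penalized cost is returned. ``t0 <= 0`` requests
    the auto rule: standard deviation of the cost deltas of 100 random
    candidate moves from the initial state (1.0 if degenerate).
    """
    np.random.seed(seed)
    sel = np.zeros(n_cells, np.uint8)
    for c in range(n_cells):
        if np.random.random() < 0.5:
            sel[c] = 1
    rep = np.zeros(n_species, np.int64)
    for c in range(n_cells):
        if sel[c] == 1:
            for k in range(indptr[c], indptr[c + 1]):
                rep[indices[k]] += 1
    shortfall = 0
    for s in range(n_species):
        d = targets[s] - rep[s]
        if d > 0:
            shortfall += d
    cost = float(sel.sum()) + spf * shortfall

    if t0 <= 0.0:
        deltas = np.empty(100)
        for i in range(100):
            c = np.random.randint(n_cells)
            deltas[i] = _toggle_delta(c, sel, rep, targets, indptr, indices, spf)
        t0 = deltas.std()
        if t0 <= 0.0:
            t0 = 1.0

    best = sel.copy()
    best_cost = cost
    temp = t0
    for it in range(iterations):
        c = np.random.randint(n_cells)
        d = _toggle_delta(c, sel, rep, targets, indptr, indices, spf)
        if d <= 0.0 or np.random.random() < np.exp(-d / temp):
            _apply_toggle(c, sel, rep, indptr, indices)
            cost += d
            if cost < best_cost - 1e-9:
                best_cost = cost
                best[:] = sel
        if (it + 1) % interval == 0:
            temp *= cooling
            if temp < 1e-12:
                temp = 1e-12
    return best, best_cost


@njit(cache=True)
def _remove_cell(c, rep, targets, indptr, indices):
    # returns covered-count delta of removing cell c
    d = 0
    for k in range(indptr[c], indptr[c + 1]):
        s = indices[k]
        if rep[s] == targets[s]:
            d -= 1
        rep[s] -= 1
    return d


@njit(cache=True)
def _add_cell(c, rep, targets, indptr, indices):
    # returns covered-count delta of adding cell c
    d = 0
    for k in range(indptr[c], indptr[c + 1]):
        s = indices[k]
        rep[s] += 1
        if rep[s] == targets[s]:
            d += 1
    return d


@njit(cache=True)
def anneal_max_coverage(indptr, indices, targets, n_cells, n_species, budget,
                        iterations, t0, cooling, interval, seed):
    """One annealing restart for the budget-constrained coverage problem.

    The selection size is pinned at ``budget``; a move swaps one
    selected cell for one unselected cell, maximizing the number of
    in-scope species meeting their targets. Ties in covered-species
    count are broken lexicographically toward selections with more
    total in-scope presences (epsilon-weighted, so the primary
    objective is never traded away), which collapses the large plateau
    of equivalent optima to near-canonical solutions. Returns the
    best-ever selection and its covered-species count.
    """
    np.random.seed(seed)
    # cell degree = in-scope presences per cell; epsilon keeps the
    # secondary term strictly below any unit change in coverage
    total_presence = indptr[n_cells]
    eps = 0.5 / (1.0 + total_presence)
    perm = np.arange(n_cells)
    for i in range(budget):
        j = i + np.random.randint(n_cells - i)
        tmp = perm[i]
        perm[i] = perm[j]
        perm[j] = tmp
    sel_list = perm[:budget].copy()
    unsel_list = perm[budget:].copy()

    rep = np.zeros(n_species, np.int64)
    for i in range(budget):
        c = sel_list[i]
        for k in range(indptr[c], indptr[c + 1]):
            rep[indices[k]] += 1
    covered = 0
    for s in range(n_species):
        if rep[s] >= targets[s]:
            covered += 1

    sumdeg = 0
    for i in range(budget):
        c = sel_list[i]
        sumdeg += indptr[c + 1] - indptr[c]

    n_unsel = n_cells - budget
    if t0 <= 0.0:
        deltas = np.empty(100)
        for i in range(100):
            si = np.random.randint(budget)
            uj = np.random.randint(n_unsel)
            old = sel_list[si]
            new = unsel_list[uj]
            d = _remove_cell(old, rep, targets, indptr, indices)
            d += _add_cell(new, rep, targets, indptr, indices)
            deltas[i] = d
            # revert
            _remove_cell(new, rep, targets, indptr, indices)
            _add_cell(old, rep, targets, indptr, indices)
        t0 = deltas.std()
        if t0 <= 0.0:
            t0 = 1.0

    best = np.sort(sel_list)
    best_covered = covered
    best_obj = covered + eps * sumdeg
    temp = t0
    for it in range(iterations):
        si = np.random.randint(budget)
        uj = np.random.randint(n_unsel)
        old = sel_list[si]
        new = unsel_list[uj]
        dcov = _remove_cell(old, rep, targets, indptr, indices)
        dcov += _add_cell(new, rep, targets, indptr, indices)
        ddeg = (indptr[new + 1] - indptr[new]) - (indptr[old + 1] - indptr[old])
        d = dcov + eps * ddeg
        if d >= 0 or np.random.random() < np.exp(d / temp):
            sel_list[si] = new
            unsel_list[uj] = old
            covered += dcov
            sumdeg += ddeg
            obj = covered + eps * sumdeg
            if obj > best_obj:
                best_obj = obj
                best_covered = covered
                best = np.sort(sel_list)
        else:
            _remove_cell(new, rep, targets, indptr, indices)
            _add_cell(old, rep, targets, indptr, indices)
        if (it + 1) % interval == 0:
            temp *= cooling
            if temp < 1e-12:
                temp = 1e-12
    return best, best_covered
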