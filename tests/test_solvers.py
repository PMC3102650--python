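import numpy as np
import pytest

from surrosel.solvers import (
    AnnealSchedule,
    ProblemSpec,
    anneal,
    brute_force,
    capped_targets,
    greedy_min_cover,
    min_cover_cost,
)

from conftest import FAST_SCHEDULE, make_matrix, random_instance


class TestCappedTargets:
    def test_capping_at_occupancy(self):
        m = make_matrix([[1, 1, 0, 0], [1, 1, 1, 1]])
        t = capped_targets(m, 3)
        assert t.tolist() == [2, 3]

    def test_goal_one_gives_all_ones(self):
        m = make_matrix([[1, 0], [1, 1]])
        assert (capped_targets(m, 1) == 1).all()

    def test_goal_below_one_rejected(self):
        m = make_matrix([[1, 0]])
        with pytest.raises(ValueError):
            capped_targets(m, 0)


class TestMinCoverCost:
    def test_feasible_selection_costs_its_size(self):
        m = make_matrix(np.ones((3, 8)))
        t = capped_targets(m, 3)
        assert min_cover_cost(range(8), m, t, spf=10) == 8.0

    def test_empty_selection_pure_penalty(self):
        m = make_matrix([[1, 0], [0, 1], [1, 1]])
        t = capped_targets(m, 1)
        assert min_cover_cost([], m, t, spf=10) == 30.0

    def test_hand_computed_partial_penalty(self):
        # selection {0}: s0 ok (target 1), s1 short by 1, s2 short by 1 of 2
        m = make_matrix([[1, 0, 0], [0, 1, 0], [1, 0, 1]])
        t = capped_targets(m, 2)  # targets 1, 1, 2
        assert min_cover_cost([0], m, t, spf=5) == 1 + 5 * (1 + 1)


class TestGreedy:
    def test_three_cell_instance(self):
        # c0:{s1,s2}, c1:{s2}, c2:{s3}; unit targets -> {c0, c2}
        m = make_matrix([[1, 0, 0], [1, 1, 0], [0, 0, 1]], species=["s1", "s2", "s3"])
        sol = greedy_min_cover(m, capped_targets(m, 1))
        assert set(sol.cells) == {0, 2}
        assert sol.feasible

    def test_dominant_cell_selected_alone(self):
        m = make_matrix([[1, 1, 0], [1, 0, 1], [1, 0, 0]])
        sol = greedy_min_cover(m, capped_targets(m, 1))
        assert sol.cells == (0,)

    def test_targets_equal_occupancy_forces_every_occupied_cell(self):
        m = make_matrix([[1, 1, 0], [0, 1, 1]])
        occ = m.occupancy()
        sol = greedy_min_cover(m, occ)
        assert set(sol.cells) == {0, 1, 2}


class TestBruteForce:
    def test_refuses_large_instances(self):
        m = make_matrix(np.ones((2, 21)))
        with pytest.raises(ValueError, match="20"):
            brute_force(ProblemSpec(matrix=m, targets=capped_targets(m, 1), mode="min_set"))

    def test_dominant_cell(self):
        m = make_matrix([[1, 1], [1, 0]])
        sol = brute_force(ProblemSpec(matrix=m, targets=capped_targets(m, 1), mode="min_set"))
        assert sol.cells == (0,)

    def test_never_worse_than_greedy(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            m = random_instance(rng, max_cells=10)
            t = capped_targets(m, int(rng.integers(1, 4)))
            bf = brute_force(ProblemSpec(matrix=m, targets=t, mode="min_set"))
            assert bf.n_cells <= greedy_min_cover(m, t).n_cells

    def test_budget_zero_covers_nothing(self):
        m = make_matrix([[1, 0], [0, 1]])
        sol = brute_force(
            ProblemSpec(matrix=m, targets=capped_targets(m, 1), mode="max_coverage", budget=0)
        )
        assert sol.objective == 0 and sol.cells == ()


class TestAnneal:
    def test_min_set_matches_brute_force_on_small_instance(self):
        m = make_matrix([[1, 0, 0], [1, 1, 0], [0, 0, 1]])
        p = ProblemSpec(matrix=m, targets=capped_targets(m, 1), mode="min_set")
        sol = anneal(p, FAST_SCHEDULE, rng=0)
        assert sol.feasible and sol.n_cells == 2

    def test_max_coverage_budget_one_picks_best_cell(self):
        # c0:{s1,s2}, c1:{s3}: the two-species cell wins
        m = make_matrix([[1, 0], [1, 0], [0, 1]])
        p = ProblemSpec(matrix=m, targets=capped_targets(m, 1), mode="max_coverage", budget=1)
        sol = anneal(p, FAST_SCHEDULE, rng=0)
        assert sol.cells == (0,) and sol.objective == 2

    def test_max_coverage_saturation_at_full_budget(self):
        m = make_matrix([[1, 1, 0], [0, 1, 1], [1, 0, 0]])
        p = ProblemSpec(matrix=m, targets=capped_targets(m, 2), mode="max_coverage", budget=3)
        sol = anneal(p, FAST_SCHEDULE, rng=0)
        assert sol.objective == 3  # every capped target reachable

    def test_never_exceeds_budget_and_monotone_in_budget(self):
        rng = np.random.default_rng(2)
        m = random_instance(rng, max_cells=10, max_species=8)
        t = capped_targets(m, 2)
        last = -1
        for budget in (1, 2, 3, 5, 8):
            p = ProblemSpec(matrix=m, targets=t, mode="max_coverage", budget=budget)
            sol = anneal(p, FAST_SCHEDULE, rng=3)
            assert sol.n_cells <= budget
            assert sol.objective >= last
            last = sol.objective

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        m = random_instance(rng)
        t = capped_targets(m, 2)
        for mode, budget in (("min_set", None), ("max_coverage", 3)):
            p = ProblemSpec(matrix=m, targets=t, mode=mode, budget=budget)
            s1 = anneal(p, FAST_SCHEDULE, rng=123)
            s2 = anneal(p, FAST_SCHEDULE, rng=123)
            assert s1.cells == s2.cells
            assert s1.objective == s2.objective
            assert s1.seed == s2.seed


class TestProblemSpec:
    def test_uncapped_targets_rejected(self):
        m = make_matrix([[1, 0]])
        with pytest.raises(ValueError, match="cap"):
            ProblemSpec(matrix=m, targets=m.occupancy() + 1, mode="min_set")

    def test_max_coverage_requires_budget(self):
        m = make_matrix([[1, 0]])
        with pytest.raises(ValueError, match="budget"):
            ProblemSpec(matrix=m, targets=capped_targets(m, 1), mode="max_coverage")

    def test_budget_above_cell_count_rejected(self):
        m = make_matrix([[1, 0]])
        with pytest.raises(ValueError):
            ProblemSpec(matrix=m, targets=capped_targets(m, 1), mode="max_coverage", budget=3)


def test_schedule_validation():
    with pytest.raises(ValueError):
        AnnealSchedule(iterations=0)
    with pytest.raises(ValueError):
        AnnealSchedule(cooling=1.0)
    with pytest.raises(ValueError):
        AnnealSchedule(restarts=0)
    assert AnnealSchedule(iterations=50_000).effective_interval == 500
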