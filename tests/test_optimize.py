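"""Feasibility checking, CGS selection, local search, and the exhaustive oracle."""

import numpy as np
import pytest

from pvlas import (
    LookAheadSpec,
    MatingPlan,
    check_feasibility,
    exhaustive_search,
    gebv,
    initial_feasible_plan,
    local_search,
    select_cgs,
    select_with_method,
)
from pvlas.errors import ConstraintError, SizeError

from conftest import ohv_plan_objective


class TestCheckFeasibility:
    def test_disjoint_pairs_are_feasible(self):
        plan = MatingPlan([(0, 1), (2, 3)], N=6)
        assert check_feasibility(plan, 6, 2) == []

    def test_asymmetric_matrix_violates_symmetry(self):
        Y = np.zeros((3, 3), dtype=int)
        Y[0, 1] = 1  # y_01 != y_10
        plan = MatingPlan([(0, 1)], N=3, x=np.array([1, 1, 0]), Y=Y)
        violations = check_feasibility(plan, 3, 1)
        assert any(v.startswith("(8)") for v in violations)

    def test_selected_but_unmated_violates_linkage(self):
        plan = MatingPlan([(0, 1)], N=4)
        x = plan.x.copy()
        x[3] = 1  # selected with an all-zero mating row
        bad = MatingPlan([(0, 1)], N=4, x=x, Y=plan.Y)
        violations = check_feasibility(bad, 4, 1)
        assert any(v.startswith("(6)") for v in violations)

    def test_wrong_cross_count_violates_total(self):
        plan = MatingPlan([(0, 1)], N=4)
        violations = check_feasibility(plan, 4, 2)
        assert any(v.startswith("(7)") for v in violations)

    def test_selfing_plan_is_feasible(self):
        plan = MatingPlan([(2, 2)], N=4)
        assert check_feasibility(plan, 4, 1) == []


class TestSelectCgs:
    def test_unambiguous_truncation(self, rng):
        v = np.array([9.0, 8.0, 7.0, 6.0, 5.0, 4.0])
        for _ in range(10):
            plan = select_cgs(v, 2, rng)
            assert sorted({p for pair in plan.pairs for p in pair}) == [0, 1, 2, 3]
            assert check_feasibility(plan, 6, 2) == []

    def test_single_cross_takes_top_two(self, rng):
        plan = select_cgs(np.array([1.0, 5.0, 3.0]), 1, rng)
        assert plan.pairs == [(1, 2)]

    def test_random_matching_is_uniform(self):
        # the 3 perfect matchings of {0,1,2,3} each appear ~1/3 of the time
        v = np.array([9.0, 8.0, 7.0, 6.0, 5.0, 4.0])
        rng = np.random.default_rng(42)
        counts = {}
        for _ in range(1000):
            plan = select_cgs(v, 2, rng)
            key = tuple(sorted(plan.pairs))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        for n in counts.values():
            assert n / 1000 == pytest.approx(1 / 3, abs=0.05)

    def test_too_few_individuals_rejected(self, rng):
        with pytest.raises(ConstraintError):
            select_cgs(np.array([1.0, 2.0, 3.0]), 2, rng)


class TestInitialFeasiblePlan:
    def test_rank_pairing(self, small_population):
        founders, trait, _ = small_population
        v = gebv(founders, trait)
        order = np.argsort(-v, kind="stable")
        plan = initial_feasible_plan(founders, trait, 2)
        assert plan.pairs[0] == tuple(sorted((order[0], order[1])))
        assert plan.pairs[1] == tuple(sorted((order[2], order[3])))
        assert check_feasibility(plan, founders.n_individuals, 2) == []


class TestLocalSearch:
    def test_trace_strictly_increases_with_deterministic_objective(
        self, small_population, rng
    ):
        founders, trait, _ = small_population
        objective = ohv_plan_objective(founders, trait)
        start = initial_feasible_plan(founders, trait, 2)
        plan, trace = local_search(
            objective, start, founders.n_individuals, 2, rng, return_trace=True
        )
        assert all(a < b for a, b in zip(trace, trace[1:]))
        assert objective(plan) >= objective(start)
        assert check_feasibility(plan, founders.n_individuals, 2) == []

    def test_reaches_exhaustive_optimum_on_tiny_instance(self):
        rng_data = np.random.default_rng(8)
        from pvlas import generate_effects, generate_founders

        founders = generate_founders(4, 10, rng=rng_data, inbred=False)
        trait = generate_effects(10, sparsity=0.8, rng=rng_data)
        objective = ohv_plan_objective(founders, trait)
        best = exhaustive_search(objective, 4, 1)
        start = initial_feasible_plan(founders, trait, 1)
        found = local_search(objective, start, 4, 1, np.random.default_rng(2))
        assert objective(found) == pytest.approx(objective(best))

    def test_global_optimum_is_fixed_point(self):
        rng_data = np.random.default_rng(9)
        from pvlas import generate_effects, generate_founders

        founders = generate_founders(5, 8, rng=rng_data, inbred=False)
        trait = generate_effects(8, sparsity=0.9, rng=rng_data)
        objective = ohv_plan_objective(founders, trait)
        best = exhaustive_search(objective, 5, 1)
        found = local_search(objective, best, 5, 1, np.random.default_rng(3))
        assert found == best

    def test_infeasible_start_rejected(self, rng):
        bad = MatingPlan([(0, 1)], N=4)
        with pytest.raises(ConstraintError):
            local_search(lambda p, s=None: 0.0, bad, 4, 2, rng)


class TestExhaustiveSearch:
    def test_enumerates_three_plans_for_two_individuals(self):
        seen = []
        exhaustive_search(lambda plan: seen.append(tuple(plan.pairs)) or 0.0, 2, 1)
        assert sorted(seen) == [((0, 0),), ((0, 1),), ((1, 1),)]

    def test_prefers_selfing_the_best_individual(self):
        v = np.array([5.0, 1.0])

        def parent_sum(plan):
            return float(sum(v[i] + v[j] for i, j in plan.pairs))

        assert exhaustive_search(parent_sum, 2, 1).pairs == [(0, 0)]

    def test_size_guard(self):
        with pytest.raises(SizeError):
            exhaustive_search(lambda plan: 0.0, 100, 5)

    def test_dominates_local_search(self):
        rng_data = np.random.default_rng(10)
        from pvlas import generate_effects, generate_founders

        for seed in range(3):
            founders = generate_founders(6, 12, rng=rng_data, inbred=False)
            trait = generate_effects(12, sparsity=0.8, rng=rng_data)
            objective = ohv_plan_objective(founders, trait)
            best = exhaustive_search(objective, 6, 2)
            start = initial_feasible_plan(founders, trait, 2)
            found = local_search(objective, start, 6, 2, np.random.default_rng(seed))
            assert objective(best) >= objective(found) - 1e-12


class TestSelectWithMethod:
    def test_cgs_dispatch_matches_select_cgs(self, small_population):
        founders, trait, gmap = small_population
        spec = LookAheadSpec(W=2, K=50)
        plan = select_with_method(
            founders, trait, gmap, "cgs", 2, spec, np.random.default_rng(7)
        )
        direct = select_cgs(gebv(founders, trait), 2, np.random.default_rng(7))
        assert plan == direct

    def test_window_one_pvlas_equals_horizon_one_las(self, small_population):
        founders, trait, gmap = small_population
        spec = LookAheadSpec(W=1, discount=0.4, gamma=0.8, K=200)
        plan_pv = select_with_method(
            founders, trait, gmap, "pvlas", 2, spec, np.random.default_rng(13)
        )
        plan_las = select_with_method(
            founders, trait, gmap, "las", 2, spec, np.random.default_rng(13), horizon=1
        )
        assert plan_pv == plan_las

    @pytest.mark.parametrize("method,horizon", [("cgs", None), ("las", 3), ("pvlas", None)])
    def test_emitted_plans_are_feasible(self, small_population, method, horizon):
        founders, trait, gmap = small_population
        spec = LookAheadSpec(W=2, discount=0.1, gamma=0.8, K=100)
        plan = select_with_method(
            founders, trait, gmap, method, 2, spec, np.random.default_rng(5),
            horizon=horizon,
        )
        assert check_feasibility(plan, founders.n_individuals, 2) == []

    def test_unknown_method_rejected(self, small_population, rng):
        founders, trait, gmap = small_population
        with pytest.raises(ValueError, match="unknown method"):
            select_with_method(founders, trait, gmap, "ohv", 2, LookAheadSpec(), rng)
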