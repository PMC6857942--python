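"""Evolutionary engine: domination, sorting, crowding, operators, the full
elitist loop on analytic test problems, and the preferred-solution rule."""

import numpy as np
import pytest

from cardiofit.exceptions import ContractError
from cardiofit.moea import (Individual, NSGAConfig, Population,
                            crowding_distance, dominates,
                            fast_nondominated_sort, nsga2,
                            polynomial_mutation, sbx_crossover,
                            select_preferred, tournament_select)


def pop(objectives):
    return Population([Individual(x=np.zeros(1), objectives=np.asarray(o, float))
                       for o in objectives])


def brute_force_fronts(F):
    """O(N² M) reference implementation by repeated non-dominated filtering."""
    F = np.asarray(F, float)
    remaining = list(range(len(F)))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            if not any(np.all(F[j] <= F[i]) and np.any(F[j] < F[i])
                       for j in remaining if j != i):
                front.append(i)
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


class TestDominates:
    def test_strict_domination(self):
        assert dominates([1, 1], [2, 2])

    def test_incomparable_pair(self):
        assert not dominates([1, 2], [2, 1])
        assert not dominates([2, 1], [1, 2])

    def test_equal_vectors_do_not_dominate(self):
        assert not dominates([1, 1], [1, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            dominates([1, 1], [1, 1, 1])


class TestSorting:
    def test_hand_worked_fronts(self):
        fronts = fast_nondominated_sort(pop([(1, 2), (2, 1), (2, 2), (3, 3)]))
        assert [sorted(f) for f in fronts] == [[0, 1], [2], [3]]

    def test_identical_objectives_share_one_front(self):
        fronts = fast_nondominated_sort(pop([(1, 1)] * 5))
        assert len(fronts) == 1 and len(fronts[0]) == 5

    def test_single_objective_chain_gives_singleton_fronts(self):
        fronts = fast_nondominated_sort(pop([(3,), (1,), (2,)]))
        assert [list(f) for f in fronts] == [[1], [2], [0]]

    def test_ranks_are_assigned(self):
        p = pop([(1, 2), (2, 1), (2, 2)])
        fast_nondominated_sort(p)
        assert [ind.rank for ind in p.individuals] == [1, 1, 2]

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(2, 31)
            m = rng.integers(1, 4)
            F = np.round(rng.random((n, m)), 2)  # duplicates likely
            fronts = fast_nondominated_sort(pop(F))
            assert [sorted(f) for f in fronts] == brute_force_fronts(F)


class TestCrowding:
    def test_small_fronts_are_all_infinite(self):
        assert np.all(np.isinf(crowding_distance([[1, 2], [2, 1]])))
        assert np.all(np.isinf(crowding_distance([[1, 2]])))

    def test_single_objective_hand_value(self):
        d = crowding_distance([[1.0], [2.0], [4.0]])
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(1.0)

    def test_duplicate_interior_points_stay_finite(self):
        d = crowding_distance([[1, 1], [2, 2], [2, 2], [3, 3]])
        assert np.all(np.isfinite(d[1:3]))

    def test_zero_span_objective_contributes_nothing(self):
        d = crowding_distance([[1, 5], [2, 5], [3, 5], [4, 5]])
        assert d[1] == pytest.approx((3 - 1) / 3)


class TestTournament:
    def make(self, rank, crowding):
        return Individual(x=np.zeros(1), objectives=np.zeros(1),
                          rank=rank, crowding=crowding)

    def test_lower_rank_wins(self, rng):
        a, b = self.make(1, 0.0), self.make(2, np.inf)
        assert tournament_select(a, b, rng) is a

    def test_larger_crowding_breaks_rank_ties(self, rng):
        a, b = self.make(1, np.inf), self.make(1, 0.5)
        assert tournament_select(a, b, rng) is a
        assert tournament_select(b, a, rng) is a  # order-independent

    def test_full_tie_is_a_fair_coin(self, rng):
        a, b = self.make(1, 1.0), self.make(1, 1.0)
        wins_a = sum(tournament_select(a, b, rng) is a for _ in range(10_000))
        assert abs(wins_a / 10_000 - 0.5) < 0.02


class TestVariationOperators:
    LB, UB = np.full(5, -1.0), np.full(5, 2.0)

    def test_sbx_children_sum_to_parents(self, rng):
        """Before clipping, SBX is symmetric about the parents' mean."""
        p1 = rng.uniform(0.0, 1.0, 5)
        p2 = rng.uniform(0.0, 1.0, 5)
        c1, c2 = sbx_crossover(p1, p2, 20.0, self.LB, self.UB, 1.0, rng)
        assert np.allclose(c1 + c2, p1 + p2, atol=1e-12)

    def test_sbx_large_index_concentrates_on_parents(self, rng):
        p1 = np.full(5, 0.2)
        p2 = np.full(5, 0.7)
        for _ in range(200):
            c1, c2 = sbx_crossover(p1, p2, 1e6, self.LB, self.UB, 1.0, rng)
            assert np.all(np.minimum(np.abs(c1 - p1), np.abs(c1 - p2)) < 1e-3)

    def test_sbx_respects_bounds(self, rng):
        for _ in range(10_000 // 50):
            p1 = rng.uniform(-1, 2, 5)
            p2 = rng.uniform(-1, 2, 5)
            for c in sbx_crossover(p1, p2, 2.0, self.LB, self.UB, 0.9, rng):
                assert np.all(c >= self.LB) and np.all(c <= self.UB)

    def test_mutation_probability_zero_is_identity(self, rng):
        x = rng.uniform(-1, 2, 5)
        assert np.array_equal(
            polynomial_mutation(x, 20.0, self.LB, self.UB, 0.0, rng), x)

    def test_mutation_large_index_stays_close(self, rng):
        x = rng.uniform(-0.9, 1.9, 5)
        for _ in range(200):
            y = polynomial_mutation(x, 1e6, self.LB, self.UB, 1.0, rng)
            assert np.all(np.abs(y - x) < 1e-3)

    def test_mutation_never_leaves_the_box(self, rng):
        x = self.LB.copy()  # start on a bound
        for _ in range(10_000 // 5):
            y = polynomial_mutation(x, 5.0, self.LB, self.UB, 1.0, rng)
            assert np.all(y >= self.LB) and np.all(y <= self.UB)


class TestNsga2Loop:
    def test_biobjective_front_covers_analytic_pareto_set(self):
        """f = (x², (x-2)²): the Pareto set is x ∈ [0, 2]."""
        cfg = NSGAConfig(pop_size=50, max_evaluations=2500, seed=7,
                         lb=np.array([-5.0]), ub=np.array([5.0]))
        front, _ = nsga2(lambda x: np.array([x[0] ** 2, (x[0] - 2) ** 2]), cfg)
        xs = np.sort([ind.x[0] for ind in front])
        assert xs[0] >= -0.01 and xs[-1] <= 2.01
        assert xs[-1] - xs[0] >= 0.8 * 2.0  # spread covers >= 80 % of [0, 2]

    def test_single_objective_sphere_converges(self):
        cfg = NSGAConfig(pop_size=50, max_evaluations=5000, seed=3,
                         lb=np.zeros(4), ub=np.ones(4))
        front, history = nsga2(
            lambda x: np.array([np.sum((x - 0.5) ** 2)]), cfg)
        best = np.array([h[0] for h in history])
        assert np.all(np.diff(best) <= 1e-15)  # elitism: never gets worse
        assert best[-1] < 1e-3

    def test_population_size_is_constant(self):
        sizes = []
        cfg = NSGAConfig(pop_size=20, max_evaluations=100, seed=1,
                         lb=np.zeros(2), ub=np.ones(2))
        nsga2(lambda x: np.array([x[0], 1 - x[0] + x[1]]), cfg,
              callback=lambda gen, p: sizes.append(len(p)))
        assert sizes == [20] * len(sizes)

    def test_final_front_is_mutually_non_dominated(self):
        cfg = NSGAConfig(pop_size=24, max_evaluations=240, seed=11,
                         lb=np.array([-5.0]), ub=np.array([5.0]))
        front, _ = nsga2(lambda x: np.array([x[0] ** 2, (x[0] - 2) ** 2]), cfg)
        F = [ind.objectives for ind in front]
        for i, fi in enumerate(F):
            for j, fj in enumerate(F):
                assert i == j or not dominates(fi, fj)

    def test_identical_seed_reproduces_the_front(self):
        cfg = NSGAConfig(pop_size=16, max_evaluations=160, seed=5,
                         lb=np.zeros(3), ub=np.ones(3))
        f = lambda x: np.array([np.sum(x ** 2), np.sum((x - 1) ** 2)])
        front1, hist1 = nsga2(f, cfg)
        front2, hist2 = nsga2(f, cfg)
        assert np.array_equal(np.array([i.x for i in front1]),
                              np.array([i.x for i in front2]))
        assert np.array_equal(np.array(hist1), np.array(hist2))

    def test_max_evaluations_must_divide_by_population(self):
        with pytest.raises(ValueError):
            NSGAConfig(pop_size=30, max_evaluations=100)


class TestSelectPreferred:
    def test_single_solution(self):
        assert select_preferred([[1.0, 2.0]]) == 0

    def test_hand_worked_knee(self):
        """Normalized sums are (1, 0.5, 1): the middle solution wins."""
        assert select_preferred([[1, 3], [1.5, 1.5], [3, 1]]) == 1

    def test_argmin_invariant_to_global_denominator(self, rng):
        for _ in range(100):
            F = rng.random((rng.integers(2, 12), rng.integers(1, 4)))
            n, m = F.shape
            s = np.zeros(n)
            for k in range(m):
                fmin, fmax = F[:, k].min(), F[:, k].max()
                if fmax > fmin:
                    s += (fmin - F[:, k]) / (fmin - fmax)
            assert select_preferred(F) == int(np.argmin(s))

    def test_empty_front_rejected(self):
        with pytest.raises(ContractError):
            select_preferred(np.empty((0, 2)))
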