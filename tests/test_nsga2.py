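import numpy as np
import pytest

from berryopt.errors import InvalidInputError
from berryopt.nsga2 import (
    NSGA2Config,
    OptimizationProblem,
    crowding_distance,
    dominates,
    fast_nondominated_sort,
    intermediate_crossover,
    run,
    tournament_select,
    uniform_mutation,
)


def brute_force_fronts(F):
    """Independent O(n^2 m) front peeling built on pairwise `dominates`."""
    n = len(F)
    dom = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j:
                dom[i][j] = dominates(F[i], F[j])
    remaining = set(range(n))
    fronts = []
    while remaining:
        front = sorted(
            i for i in remaining
            if not any(dom[j][i] for j in remaining if j != i)
        )
        fronts.append(front)
        remaining -= set(front)
    return fronts


class TestDominates:
    def test_strict_improvement_everywhere(self):
        assert dominates((1, 1), (2, 2))

    def test_incomparable_pair(self):
        assert not dominates((1, 2), (2, 1))
        assert not dominates((2, 1), (1, 2))

    def test_point_never_dominates_itself(self):
        assert not dominates((1.0, 2.0), (1.0, 2.0))

    def test_senses_respected(self):
        # second objective maximised: larger is better
        assert dominates((1, 5), (2, 4), senses=("min", "max"))
        assert not dominates((1, 3), (2, 4), senses=("min", "max"))

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            dominates((1,), (1, 2))


class TestFastNondominatedSort:
    def test_dominance_chain_gives_singleton_fronts(self):
        F = np.array([[3.0, 3.0], [2.0, 2.0], [1.0, 1.0]])
        fronts = fast_nondominated_sort(F)
        assert [f.tolist() for f in fronts] == [[2], [1], [0]]

    def test_mutually_incomparable_single_front(self):
        F = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        fronts = fast_nondominated_sort(F)
        assert fronts[0].tolist() == [0, 1, 2]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_on_random_points(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.random((60, 4))
        ours = [sorted(f.tolist()) for f in fast_nondominated_sort(F)]
        assert ours == brute_force_fronts(F)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            fast_nondominated_sort(np.empty((0, 2)))


class TestCrowdingDistance:
    def test_two_point_front_both_infinite(self):
        d = crowding_distance(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert np.all(np.isinf(d))

    def test_equally_spaced_collinear_interior(self):
        F = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        d = crowding_distance(F)
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_affine_rescaling_invariance(self, rng):
        F = rng.random((40, 3))
        F2 = F * np.array([10.0, 0.5, 100.0]) + np.array([5.0, -3.0, 0.0])
        d1, d2 = crowding_distance(F), crowding_distance(F2)
        finite = np.isfinite(d1)
        np.testing.assert_allclose(d1[finite], d2[finite], rtol=1e-9)

    def test_zero_range_objective_contributes_nothing(self):
        F = np.array([[0.0, 1.0], [1.0, 1.0], [2.0, 1.0]])
        d = crowding_distance(F)
        assert d[1] == pytest.approx(1.0)  # only the first objective counts


class TestOperators:
    def test_tournament_prefers_lower_rank(self, rng):
        rank = np.array([1, 2])
        crowd = np.array([0.1, 5.0])
        wins = [tournament_select(rank, crowd, rng) for _ in range(200)]
        assert set(wins) <= {0, 1}
        # whenever both candidates appear, rank 1 must win; over many draws
        # index 0 must be the majority winner
        assert wins.count(0) > wins.count(1)

    def test_tournament_breaks_rank_tie_by_crowding(self, rng):
        rank = np.array([1, 1])
        crowd = np.array([np.inf, 1.0])
        # candidates drawn may be (0,0), (1,1) mixes; crowding decides mixes
        wins = [tournament_select(rank, crowd, rng) for _ in range(300)]
        assert wins.count(0) > wins.count(1)

    def test_crossover_ratio_zero_returns_parents(self, rng):
        b = np.array([[0.0, 1.0]] * 3)
        p1, p2 = np.array([0.1, 0.2, 0.3]), np.array([0.9, 0.8, 0.7])
        c1, c2 = intermediate_crossover(p1, p2, rng, b, ratio=0.0, rate=1.0)
        np.testing.assert_array_equal(c1, p1)
        np.testing.assert_array_equal(c2, p2)

    def test_crossover_identical_parents_identical_children(self, rng):
        b = np.array([[0.0, 1.0]] * 2)
        p = np.array([0.4, 0.6])
        c1, c2 = intermediate_crossover(p, p, rng, b)
        np.testing.assert_array_equal(c1, p)
        np.testing.assert_array_equal(c2, p)

    def test_crossover_children_in_parent_box(self, rng):
        b = np.array([[0.0, 1.0]] * 5)
        for _ in range(50):
            p1, p2 = rng.random(5), rng.random(5)
            c1, c2 = intermediate_crossover(p1, p2, rng, b, ratio=1.0, rate=1.0)
            lo, hi = np.minimum(p1, p2), np.maximum(p1, p2)
            for c in (c1, c2):
                assert np.all(c >= lo - 1e-12) and np.all(c <= hi + 1e-12)

    def test_mutation_rate_zero_identity(self, rng):
        b = np.array([[0.0, 1.0]] * 4)
        x = rng.random(4)
        np.testing.assert_array_equal(uniform_mutation(x, rng, b, rate=0.0), x)

    def test_mutation_rate_one_uniform_within_bounds(self, rng):
        b = np.array([[2.0, 3.0], [-1.0, 0.0]])
        draws = np.array([uniform_mutation(np.array([2.5, -0.5]), rng, b, rate=1.0)
                          for _ in range(2000)])
        assert draws[:, 0].min() >= 2.0 and draws[:, 0].max() <= 3.0
        assert abs(draws[:, 0].mean() - 2.5) < 0.03
        assert abs(draws[:, 1].mean() + 0.5) < 0.03

    def test_mutated_gene_fraction_matches_rate(self, rng):
        # Monte-Carlo estimate of the per-gene mutation probability against
        # its binomial standard error
        b = np.array([[0.0, 1.0]])
        n = 100_000
        x = np.full(1, 0.5)
        flipped = sum(
            uniform_mutation(x, rng, b, rate=0.10)[0] != 0.5 for _ in range(n)
        )
        assert flipped / n == pytest.approx(0.10, abs=0.003)


class TestRun:
    @staticmethod
    def biobjective():
        def obj(X):
            x = X[:, 0]
            return np.column_stack([x ** 2, (x - 2.0) ** 2])

        return OptimizationProblem(
            objective=obj, senses=("min", "min"), bounds=np.array([[-5.0, 5.0]])
        )

    def test_biobjective_front_on_segment(self):
        # analytic Pareto set is x in [0, 2]
        cfg = NSGA2Config(generations_per_var=120, stall_generations=30,
                          front_size=20, seed=5)
        res = run(self.biobjective(), cfg, seed=5)
        assert np.all(res.X >= -0.05) and np.all(res.X <= 2.05)

    def test_constant_objectives_single_front(self):
        def obj(X):
            return np.ones((len(X), 2))

        prob = OptimizationProblem(obj, ("min", "min"), np.array([[0.0, 1.0]]))
        cfg = NSGA2Config(generations_per_var=10, front_size=5, seed=0,
                          polish_radii=(0.05,))
        res = run(prob, cfg, seed=0)
        assert len(res.X) >= 1
        assert np.all(res.F == 1.0)

    def test_seeded_determinism(self):
        cfg = NSGA2Config(generations_per_var=40, front_size=10, seed=9)
        a = run(self.biobjective(), cfg, seed=9)
        b = run(self.biobjective(), cfg, seed=9)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.F, b.F)

    def test_bounds_respected(self):
        cfg = NSGA2Config(generations_per_var=40, front_size=10, seed=2)
        res = run(self.biobjective(), cfg, seed=2)
        assert np.all(res.X >= -5.0) and np.all(res.X <= 5.0)

    def test_max_sense_sign_roundtrip(self):
        # maximising -x^2 is the same as minimising x^2; reported values
        # must be on the caller's scale (negative, peak at 0)
        def obj(X):
            x = X[:, 0]
            return np.column_stack([-(x ** 2), (x - 1.0) ** 2])

        prob = OptimizationProblem(obj, ("max", "min"), np.array([[-2.0, 2.0]]))
        cfg = NSGA2Config(generations_per_var=60, front_size=10, seed=3)
        res = run(prob, cfg, seed=3)
        assert res.F[:, 0].max() <= 0.0
        assert np.any(res.F[:, 0] > -0.01)

    def test_nonfinite_objective_identified(self):
        def obj(X):
            F = np.ones((len(X), 2))
            F[X[:, 0] > 0.5] = np.nan
            return F

        prob = OptimizationProblem(obj, ("min", "min"), np.array([[0.0, 1.0]]))
        with pytest.raises(InvalidInputError, match="non-finite"):
            run(prob, NSGA2Config(generations_per_var=5, seed=0), seed=0)

    def test_returned_front_mutually_nondominated(self):
        cfg = NSGA2Config(generations_per_var=60, front_size=15, seed=4)
        res = run(self.biobjective(), cfg, seed=4)
        for i in range(len(res.F)):
            for j in range(len(res.F)):
                if i != j:
                    assert not dominates(res.F[i], res.F[j])
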