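"""Adaptive mechanisms: distance ratios, gray analysis, alpha strategies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adafa import AdaptiveConfig, FAConfig, SearchSpace, attractiveness, run_adafa
from adafa.adaptive import (
    STRATEGIES,
    adaptive_attractiveness,
    adaptive_gamma,
    alpha_schedule,
    compute_distance_state,
    compute_gray_state,
    distance_ratio,
    gray_coefficient,
    gray_deltas,
    gray_relational_coefficient,
    gray_relational_grade,
    heterogeneous_update,
    mean_distance,
    randomization_term,
    run_adafa,
)
from adafa.benchmarks import get_problem


class TestMeanDistance:
    def test_coincident_swarm_is_zero(self):
        pos = np.ones((4, 3))
        assert mean_distance(0, pos) == 0.0

    def test_collinear_brute_force(self):
        pos = np.array([[0.0], [1.0], [2.0]])
        # explicit enumeration for the middle point
        brute = (1.0 + 1.0) / 2
        assert mean_distance(1, pos) == pytest.approx(brute)
        assert mean_distance(0, pos) == pytest.approx((1.0 + 2.0) / 2)

    def test_translation_invariance(self, rng):
        pos = rng.normal(size=(6, 4))
        shifted = pos + 13.7
        for i in range(6):
            assert mean_distance(i, pos) == pytest.approx(mean_distance(i, shifted))

    def test_single_firefly_raises(self):
        with pytest.raises(ValueError):
            mean_distance(0, np.zeros((1, 3)))


class TestDistanceRatio:
    def test_all_ratios_finite(self, rng):
        pos = rng.normal(size=(8, 3))
        state = compute_distance_state(pos, pos[0])
        assert np.all(np.isfinite([distance_ratio(state, i) for i in range(8)]))

    def test_hand_built_extremes(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        best = np.array([0.0, 0.0])
        state = compute_distance_state(pos, best)
        # d_min = 1 (pair 0-1), d_max = 3 (pair 0-2)
        assert state.d_min == 1.0 and state.d_max == 3.0
        assert distance_ratio(state, 1) == pytest.approx(0.0)   # d_best=1=d_min
        assert distance_ratio(state, 2) == pytest.approx(1.0)   # d_best=3=d_max

    def test_collapsed_swarm_returns_zero(self):
        pos = np.ones((5, 2))
        state = compute_distance_state(pos, pos[0])
        assert all(distance_ratio(state, i) == 0.0 for i in range(5))


class TestAdaptiveGamma:
    def test_monotone_in_delta_and_lam(self):
        grid = np.linspace(0.0, 1.0, 7)
        for ratio in grid:
            for lam in (0.05, 0.1, 0.5, 2.0):
                g1 = adaptive_gamma(ratio, 1.0, lam)
                g2 = adaptive_gamma(ratio, 2.0, lam)
                assert g2 < g1
            for delta in (0.5, 1.5, 3.0):
                vals = [adaptive_gamma(ratio, delta, lam) for lam in (0.05, 0.2, 1.0, 3.0)]
                assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_large_when_both_factors_small(self):
        assert adaptive_gamma(0.5, 1e-3, 1e-3) > 100.0

    def test_strictly_positive_on_grid(self):
        for d in (0.1, 1.0, 5.0):
            for l in (0.01, 0.5, 4.0):
                for r in np.linspace(0, 1, 5):
                    assert adaptive_gamma(r, d, l) > 0

    def test_invalid_factors_raise(self):
        with pytest.raises(ValueError):
            adaptive_gamma(0.5, 0.0, 1.0)

    def test_two_ratios_give_distinct_attractiveness(self):
        g1 = adaptive_gamma(0.2, 1.5, 0.1)
        g2 = adaptive_gamma(0.9, 1.5, 0.1)
        a1 = adaptive_attractiveness(1.0, g1, 0.7)
        a2 = adaptive_attractiveness(1.0, g2, 0.7)
        assert a1 != a2

    def test_reduces_to_core_attractiveness(self):
        assert adaptive_attractiveness(1.3, 0.8, 0.5) == attractiveness(1.3, 0.8, 0.5)
        assert adaptive_attractiveness(1.3, 0.8, 0.0) == 1.3


class TestGrayAnalysis:
    def test_identical_sequences_give_unit_coefficients(self):
        ref = np.array([1.0, 2.0, 3.0])
        dmin, dmax = gray_deltas(ref, np.tile(ref, (4, 1)))
        for k in range(3):
            assert gray_relational_coefficient(ref, ref, k, 0.5, dmin, dmax) == 1.0

    def test_worst_dimension_closed_form(self):
        ref = np.zeros(3)
        cmp_ = np.array([0.5, 2.0, 1.0])
        dmin, dmax = gray_deltas(ref, cmp_[None, :])
        rho = 0.5
        # at the max-delta dimension: (dmin + rho dmax) / ((1 + rho) dmax)
        expected = (dmin + rho * dmax) / (2.0 + rho * 2.0)
        assert gray_relational_coefficient(ref, cmp_, 1, rho, dmin, dmax) == pytest.approx(expected)

    def test_rho_monotone_at_worst_dimension(self):
        ref = np.zeros(2)
        cmp_ = np.array([0.1, 3.0])
        dmin, dmax = gray_deltas(ref, cmp_[None, :])
        vals = [gray_relational_coefficient(ref, cmp_, 1, r, dmin, dmax)
                for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_grade_two_term_hand_value(self):
        # uniform weights, coefficients (1, 0.5) -> 0.75
        assert gray_relational_grade(np.array([1.0, 0.5]), np.array([0.5, 0.5])) == 0.75

    def test_grade_all_ones(self):
        assert gray_relational_grade(np.ones(5), np.full(5, 0.2)) == pytest.approx(1.0)

    def test_grade_permutation_symmetry(self, rng):
        c = rng.random(6)
        w = rng.random(6)
        w /= w.sum()
        perm = rng.permutation(6)
        assert gray_relational_grade(c, w) == pytest.approx(
            gray_relational_grade(c[perm], w[perm]))

    def test_grade_weight_sum_violation(self):
        with pytest.raises(ValueError):
            gray_relational_grade(np.ones(3), np.array([0.5, 0.2, 0.1]))

    def test_gray_coefficient_bounds_and_degenerate(self):
        for grade in np.linspace(1e-6, 1.0, 13):
            v = gray_coefficient(grade, 0.4, 0.9)
            assert 0.4 <= v <= 0.9
        assert gray_coefficient(1.0, 0.4, 0.9) == 0.4     # boundary at grade 1
        assert gray_coefficient(0.3, 0.7, 0.7) == 0.7     # degenerate bounds

    def test_gray_state_unit_grade_for_collapsed_population(self):
        cfg = AdaptiveConfig()
        pos = np.tile(np.array([1.0, 2.0]), (4, 1))
        state = compute_gray_state(pos, np.array([1.0, 2.0]), cfg)
        assert np.allclose(state.grades, 1.0)
        assert np.allclose(state.coefficients, cfg.g_min)


class TestAlphaSchedules:
    T, N, D = 500, 40, 30

    def cfg(self, **kw):
        return AdaptiveConfig(**kw)

    def test_s0_is_affine(self):
        cfg = self.cfg()
        vals = [alpha_schedule("S0", t, self.T, self.N, self.D, cfg) for t in range(1, self.T + 1)]
        assert np.allclose(np.diff(vals, 2), 0.0)

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_decay_contract(self, strategy):
        cfg = self.cfg()
        a1 = alpha_schedule(strategy, 1, self.T, self.N, self.D, cfg)
        aT = alpha_schedule(strategy, self.T, self.T, self.N, self.D, cfg)
        assert aT <= a1
        assert a1 > 0

    @pytest.mark.parametrize("strategy", ["S1", "S2", "S3", "S4", "S5"])
    def test_range_exceeds_linear_strategy(self, strategy):
        cfg = self.cfg()
        ts = range(1, self.T + 1)
        rng_s = [alpha_schedule(strategy, t, self.T, self.N, self.D, cfg) for t in ts]
        rng_0 = [alpha_schedule("S0", t, self.T, self.N, self.D, cfg) for t in ts]
        assert max(rng_s) - min(rng_s) > max(rng_0) - min(rng_0)

    def test_s5_endpoint_independent_of_population_size(self):
        cfg = self.cfg()
        finals = [alpha_schedule("S5", self.T, self.T, N, self.D, cfg)
                  for N in (20, 40, 80)]
        ref = finals[0]
        assert all(abs(f - ref) / ref < 0.10 for f in finals)

    def test_unknown_strategy_raises(self):
        with pytest.raises(ValueError):
            alpha_schedule("S9", 1, 10, 5, 2, self.cfg())

    def test_generation_out_of_range(self):
        with pytest.raises(ValueError):
            alpha_schedule("S1", 0, 10, 5, 2, self.cfg())


class TestRandomizationTerm:
    def test_clamp_lower_bound(self, small_space):
        cfg = AdaptiveConfig(alpha_min=0.2, alpha_max=0.8)
        a = randomization_term(0.01, cfg, np.random.default_rng(0), small_space)
        b = randomization_term(0.2, cfg, np.random.default_rng(0), small_space)
        assert np.array_equal(a, b)

    def test_zero_width_bounds_deterministic_scale(self, small_space):
        cfg = AdaptiveConfig(alpha_min=0.3, alpha_max=0.3 + 1e-12)
        term = randomization_term(0.9, cfg, np.random.default_rng(1), small_space,
                                  scale_by_range=False)
        draws = np.random.default_rng(1).standard_normal(3)
        assert np.allclose(term, 0.3 * draws + 1e-12 * draws, atol=1e-11)

    def test_monte_carlo_mean_is_zero(self, small_space):
        cfg = AdaptiveConfig()
        rng = np.random.default_rng(42)
        n = 10_000
        terms = np.array([randomization_term(0.5, cfg, rng, small_space,
                                             scale_by_range=False) for _ in range(n)])
        se = 0.5 / np.sqrt(n)
        assert np.all(np.abs(terms.mean(axis=0)) < 3 * se)


class TestHeterogeneousUpdate:
    def setup_method(self):
        self.space = SearchSpace(3, -10.0, 10.0)
        self.fa = FAConfig(pop_size=5, max_gen=10)
        self.ada = AdaptiveConfig()
        self.xi = np.array([1.0, 2.0, 3.0])
        self.xj = np.array([0.0, 0.5, 1.0])
        self.best = np.array([-1.0, 0.0, 0.5])

    def test_branches_differ_for_generic_inputs(self):
        out0 = heterogeneous_update(self.xi, self.xj, self.best, 0.7, 0.6, 0.0,
                                    self.space, self.fa, self.ada,
                                    np.random.default_rng(0), branch=0)
        out1 = heterogeneous_update(self.xi, self.xj, self.best, 0.7, 0.6, 0.0,
                                    self.space, self.fa, self.ada,
                                    np.random.default_rng(0), branch=1)
        assert not np.allclose(out0, out1)

    def test_seed_determinism(self):
        a = heterogeneous_update(self.xi, self.xj, self.best, 0.7, 0.6, 0.3,
                                 self.space, self.fa, self.ada, np.random.default_rng(9))
        b = heterogeneous_update(self.xi, self.xj, self.best, 0.7, 0.6, 0.3,
                                 self.space, self.fa, self.ada, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_result_repaired_into_bounds(self):
        tight = SearchSpace(3, -1.0, 1.0)
        out = heterogeneous_update(np.array([0.9, 0.9, 0.9]), np.array([-0.9, 0.0, 0.9]),
                                   np.zeros(3), 0.7, 0.6, 1.0, tight, self.fa, self.ada,
                                   np.random.default_rng(2))
        assert np.all(out >= -1.0) and np.all(out <= 1.0)


class TestRunAdafa:
    def test_trace_length_and_determinism(self, sphere2d):
        fa = FAConfig(pop_size=8, max_gen=60, seed=3)
        r1 = run_adafa(sphere2d, fa)
        r2 = run_adafa(sphere2d, fa)
        assert len(r1.trace) == 60
        assert np.array_equal(r1.trace, r2.trace)

    def test_best_monotone(self, sphere2d):
        res = run_adafa(sphere2d, FAConfig(pop_size=8, max_gen=60, seed=4))
        assert np.all(np.diff(res.trace) <= 0)

    def test_interpreted_path_converges(self):
        class Shifted:
            space = SearchSpace(3, -4.0, 4.0)

            @staticmethod
            def evaluate(X, rng=None):
                X = np.atleast_2d(X)
                return np.sum((X + 0.5) ** 2, axis=1)

        res = run_adafa(Shifted(), FAConfig(pop_size=10, max_gen=120, seed=5))
        assert res.best_value < 1e-6

    def test_sphere_30d_reaches_deep_convergence(self):
        """Median final value over 10 seeds on the 30-D Sphere at the full
        budget falls far below machine-visible scales (the unimodal
        signature of the adaptive variants)."""
        p = get_problem("f1")
        vals = [run_adafa(p, FAConfig(pop_size=40, max_gen=1000, seed=s)).best_value
                for s in range(10)]
        assert np.median(vals) < 1e-20


@settings(deadline=None, max_examples=25, derandomize=True)
@given(grade=st.floats(1e-9, 1.0), g_min=st.floats(0.0, 0.5), width=st.floats(0.0, 0.5))
def test_gray_coefficient_always_bounded_property(grade, g_min, width):
    """The gray contraction weight never leaves [g_min, g_max]."""
    v = gray_coefficient(grade, g_min, g_min + width)
    assert g_min - 1e-12 <= v <= g_min + width + 1e-12
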