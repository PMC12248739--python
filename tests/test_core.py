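"""Unit and property tests for the basic whale optimizer."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from woaboost.core import (
    Population,
    SearchSpace,
    WOAConfig,
    clip_to_bounds,
    draw_coefficients,
    encircle_update,
    exploration_update,
    linear_decay_a,
    optimize,
    spiral_update,
    woa_step,
)


class TestDecaySchedule:
    @pytest.mark.parametrize(
        "t,t_max,expected", [(0, 50, 2.0), (50, 50, 0.0), (25, 50, 1.0)]
    )
    def test_linear_anchor_points(self, t, t_max, expected):
        assert linear_decay_a(t, t_max) == pytest.approx(expected)

    @pytest.mark.parametrize("t", [-1, 51])
    def test_out_of_range_iteration_rejected(self, t):
        with pytest.raises(ValueError):
            linear_decay_a(t, 50)


class TestCoefficientDraws:
    def test_ranges_over_many_draws(self):
        rng = np.random.default_rng(0)
        for t, a in [(0, 2.0), (25, 1.0), (49, 0.04)]:
            for _ in range(200):
                A, C, l, p = draw_coefficients(a, rng, 5)
                assert np.all(np.abs(A) <= a + 1e-12)
                assert np.all((C >= 0) & (C <= 2))
                assert -1 <= l <= 1
                assert 0 <= p <= 1

    def test_extremes_of_the_affine_form(self):
        # A = 2a·r − a: r=0 → −a, r=0.5 → 0, r=1 → a; C = 2r′ ∈ [0,2]
        a = 2.0
        for r, expected in [(0.0, -2.0), (0.5, 0.0), (1.0, 2.0)]:
            assert 2 * a * r - a == pytest.approx(expected)


class TestUpdateRules:
    def test_encircle_with_zero_A_returns_best(self):
        X, Xs = np.array([1.0, 4.0]), np.array([2.0, -1.0])
        out = encircle_update(X, Xs, np.zeros(2), np.ones(2))
        assert np.allclose(out, Xs)

    def test_encircle_zero_distance_fixed_point(self):
        Xs = np.array([2.0, -1.0])
        out = encircle_update(Xs, Xs, np.array([0.5, 0.5]), np.ones(2))
        assert np.allclose(out, Xs)

    def test_encircle_hand_computed(self):
        # D = |2·2 − 1| = 3; result = 2 − 0.5·3 = 0.5
        out = encircle_update(np.array([1.0]), np.array([2.0]), np.array([0.5]), np.array([2.0]))
        assert out[0] == pytest.approx(0.5)

    def test_encircle_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            encircle_update(np.ones(2), np.ones(3), np.ones(2), np.ones(2))

    def test_spiral_at_l_zero_adds_distance(self):
        X, Xs = np.array([1.0, -1.0]), np.array([3.0, 2.0])
        out = spiral_update(X, Xs, b=1.0, l=0.0)
        assert np.allclose(out, Xs + np.abs(Xs - X))

    def test_spiral_fixed_point_at_best(self):
        Xs = np.array([3.0, 2.0])
        for l in (-1.0, -0.3, 0.0, 0.7, 1.0):
            assert np.allclose(spiral_update(Xs, Xs, 1.0, l), Xs)

    def test_spiral_hand_computed(self):
        # D' = 1; e^{-1}·cos(−2π) = 1/e
        out = spiral_update(np.array([1.0]), np.array([0.0]), b=1.0, l=-1.0)
        assert out[0] == pytest.approx(np.exp(-1.0))

    def test_exploration_with_zero_A_returns_random_agent(self):
        out = exploration_update(np.array([1.0]), np.array([3.0]), np.zeros(1), np.ones(1))
        assert out[0] == pytest.approx(3.0)

    def test_exploration_self_partner_fixed_point_both_modes(self):
        X = np.array([2.0])
        for literal in (False, True):
            out = exploration_update(X, X, np.ones(1), np.ones(1), literal)
            assert out[0] == pytest.approx(2.0)

    def test_exploration_hand_computed_default_mode(self):
        # D = |3 − 1| = 2; result = 3 − 1·2 = 1
        out = exploration_update(np.array([1.0]), np.array([3.0]), np.ones(1), np.ones(1))
        assert out[0] == pytest.approx(1.0)

    def test_exploration_literal_mode_multiplies_by_position(self):
        # as-printed variant: X_rand − X∘D = 3 − 1·2 = 1 here, differs when X != A
        out = exploration_update(
            np.array([0.5]), np.array([3.0]), np.ones(1), np.ones(1), literal_equations=True
        )
        # D = |3 − 0.5| = 2.5; 3 − 0.5·2.5 = 1.75
        assert out[0] == pytest.approx(1.75)


class TestSearchSpace:
    def test_clip_projects_componentwise(self):
        space = SearchSpace([0.0, 0.0], [1.0, 5.0])
        assert np.allclose(clip_to_bounds(np.array([0.5, 7.0]), space), [0.5, 5.0])
        assert np.allclose(clip_to_bounds(np.array([-5.0, 2.0]), space), [0.0, 2.0])

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace([1.0], [1.0])

    def test_binary_codec_requires_unit_bounds(self):
        with pytest.raises(ValueError):
            SearchSpace([0.0], [2.0], codec=("binary",))


class TestOptimize:
    def test_constant_fitness_returns_constant(self):
        space = SearchSpace([-1, -1], [1, 1])
        res = optimize(space, lambda x: 7.5, WOAConfig(n_agents=5, n_iters=10, seed=0))
        assert res.best_fitness == 7.5
        assert np.all(res.history == 7.5)

    def test_single_agent_rejected(self):
        space = SearchSpace([-1], [1])
        with pytest.raises(ValueError):
            optimize(space, lambda x: 0.0, WOAConfig(n_agents=1, n_iters=5, seed=0))

    def test_seed_determinism_bit_identical(self, sphere):
        space = SearchSpace([-10] * 5, [10] * 5)
        cfg = lambda: WOAConfig(n_agents=10, n_iters=30, seed=42)
        r1 = optimize(space, sphere, cfg())
        r2 = optimize(space, sphere, cfg())
        assert np.array_equal(r1.history, r2.history)
        assert np.array_equal(r1.best_position, r2.best_position)

    def test_history_monotone_and_positions_bounded(self, sphere):
        space = SearchSpace([-10] * 5, [10] * 5)
        res = optimize(space, sphere, WOAConfig(n_agents=20, n_iters=200, seed=3))
        assert np.all(np.diff(res.history) <= 0)
        assert res.best_fitness == res.history[-1]
        assert np.all(res.best_position >= -10) and np.all(res.best_position <= 10)

    def test_elitism_beats_every_initial_agent(self):
        space = SearchSpace([-1], [1])
        init = np.linspace(-1, 1, 6).reshape(6, 1)
        f = lambda x: float(abs(x[0]))
        res = optimize(space, f, WOAConfig(n_agents=6, n_iters=20, seed=0), init_positions=init)
        assert res.best_fitness <= min(f(p) for p in init)

    def test_bowl_success_rate_across_seeds(self, sphere):
        space = SearchSpace([-10] * 5, [10] * 5)
        hits = sum(
            optimize(space, sphere, WOAConfig(n_agents=30, n_iters=200, seed=s)).best_fitness
            < 1e-2
            for s in range(10)
        )
        assert hits >= 9

    def test_non_finite_candidate_rejected_keeps_previous(self):
        space = SearchSpace([-1, -1], [1, 1])
        calls = {"n": 0}

        def f(x):
            calls["n"] += 1
            return np.nan if calls["n"] > 5 else float(np.sum(x**2))

        res = optimize(space, f, WOAConfig(n_agents=5, n_iters=4, seed=0))
        assert np.isfinite(res.best_fitness)
        assert np.all(np.diff(res.history) <= 0)

    def test_early_stop_patience_truncates_history(self):
        space = SearchSpace([-1], [1])
        res = optimize(
            space, lambda x: 1.0, WOAConfig(n_agents=3, n_iters=50, seed=0, patience=5)
        )
        assert len(res.history) == 5


@given(seed=st.integers(0, 2**16), n_iters=st.integers(1, 30))
def test_positions_stay_in_bounds_property(seed, n_iters):
    """Every agent position is inside the box after every step (any fitness)."""
    space = SearchSpace([-2.0, 0.0], [3.0, 1.0])
    rng = np.random.default_rng(seed)
    cfg = WOAConfig(n_agents=4, n_iters=n_iters, seed=seed)
    init = rng.uniform(space.lower, space.upper, size=(4, 2))
    fitness = lambda x: float(np.sin(x[0]) + x[1] ** 2)
    pop = Population(
        positions=init.copy(),
        fitness=np.array([fitness(p) for p in init]),
        best_position=init[0].copy(),
        best_fitness=fitness(init[0]),
    )
    loop_rng = np.random.default_rng(seed)
    for t in range(n_iters):
        woa_step(pop, t, cfg, space, fitness, loop_rng)
        assert np.all(pop.positions >= space.lower - 1e-12)
        assert np.all(pop.positions <= space.upper + 1e-12)
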