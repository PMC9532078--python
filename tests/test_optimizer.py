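import numpy as np
import pytest

from sparrowforge.benchmarks import evaluate, get_function
from sparrowforge.chaos import make_map
from sparrowforge.optimizer import (
    OptimizerResult,
    SparrowConfig,
    SwarmState,
    gaussian_mutate,
    run_cgssa,
    run_ssa,
    update_discoverers,
    update_followers,
    update_scouts,
)


def make_state(positions, fitness):
    positions = np.asarray(positions, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    i_best, i_worst = int(np.argmin(fitness)), int(np.argmax(fitness))
    return SwarmState(
        positions=positions.copy(),
        fitness=fitness.copy(),
        best_position=positions[i_best].copy(),
        best_fitness=float(fitness[i_best]),
        worst_position=positions[i_worst].copy(),
        worst_fitness=float(fitness[i_worst]),
    )


def small_config(**kw):
    defaults = dict(dim=2, lower_bound=-10.0, upper_bound=10.0, pop_size=4, max_iter=500)
    defaults.update(kw)
    return SparrowConfig(**defaults)


class TestDiscoverers:
    def test_safe_branch_decay_with_unit_alpha(self, forced_rng_factory):
        # rank 1, alpha forced to 1, T=500: each coordinate times exp(-1/500)
        cfg = small_config()
        state = make_state(np.ones((4, 2)), [1.0, 2.0, 3.0, 4.0])
        rng = forced_rng_factory(random_value=0.0)  # alpha = 1 - 0
        update_discoverers(state, cfg, warning_value=0.1, rng=rng, indices=np.array([0]))
        np.testing.assert_allclose(state.positions[0], np.exp(-1 / 500) * np.ones(2))
        assert state.positions[0][0] == pytest.approx(0.9980020, abs=1e-7)

    def test_danger_branch_zero_q_is_identity(self, forced_rng_factory):
        cfg = small_config()
        state = make_state(np.ones((4, 2)) * 3.0, [1.0, 2.0, 3.0, 4.0])
        rng = forced_rng_factory(normal_value=0.0)
        update_discoverers(state, cfg, warning_value=0.99, rng=rng, indices=np.array([0]))
        np.testing.assert_array_equal(state.positions[0], [3.0, 3.0])

    def test_origin_is_fixed_point_of_both_branches(self, forced_rng_factory):
        cfg = small_config()
        for warning in (0.1, 0.99):
            state = make_state(np.zeros((4, 2)), [1.0, 2.0, 3.0, 4.0])
            rng = forced_rng_factory(random_value=0.0, normal_value=0.0)
            update_discoverers(state, cfg, warning, rng, indices=np.array([0]))
            np.testing.assert_array_equal(state.positions[0], [0.0, 0.0])


class TestFollowers:
    def test_starving_branch_zero_q_gives_zero_vector(self, forced_rng_factory):
        cfg = small_config()
        state = make_state(np.ones((4, 2)) * 2.0, [1.0, 2.0, 3.0, 4.0])
        rng = forced_rng_factory(normal_value=0.0, choice_values=[1.0, 1.0])
        update_followers(state, cfg, rng, indices=np.array([2, 3]))  # ranks 1, 2 of 2
        np.testing.assert_array_equal(state.positions[3], [0.0, 0.0])  # rank 2 > 2/2

    def test_forage_branch_at_best_stays_at_best(self, forced_rng_factory):
        cfg = small_config()
        positions = np.ones((4, 2))
        state = make_state(positions, [1.0, 2.0, 3.0, 4.0])
        rng = forced_rng_factory(choice_values=[1.0, -1.0])
        update_followers(state, cfg, rng, indices=np.array([1, 2]))
        np.testing.assert_array_equal(state.positions[1], state.best_position)

    def test_forage_branch_hand_computed_step(self, forced_rng_factory):
        # A=(1,-1), |x - xb|=(2,4): step = (2*1 + 4*(-1)) / 2 = -1
        cfg = small_config()
        positions = np.array([[0.0, 0.0], [2.0, 4.0], [5.0, 5.0], [6.0, 6.0]])
        state = make_state(positions, [1.0, 2.0, 3.0, 4.0])
        rng = forced_rng_factory(choice_values=[1.0, -1.0])
        update_followers(state, cfg, rng, indices=np.array([1, 2, 3]))  # rank 1 of 3
        np.testing.assert_allclose(state.positions[1], [-1.0, -1.0])

    def test_pseudo_inverse_identity(self, rng):
        # A . A+ = 1 for random sign vectors
        for _ in range(100):
            d = rng.integers(1, 50)
            a = rng.choice([-1.0, 1.0], size=d)
            assert a @ (a / d) == pytest.approx(1.0)


class TestScouts:
    def test_non_best_zero_beta_lands_on_best(self, forced_rng_factory):
        cfg = small_config()
        state = make_state(np.arange(8.0).reshape(4, 2), [1.0, 2.0, 3.0, 4.0])
        rng = forced_rng_factory(normal_value=0.0)
        update_scouts(state, cfg, rng, indices=np.array([2]))
        np.testing.assert_array_equal(state.positions[2], state.best_position)

    def test_best_zero_k_is_identity(self, forced_rng_factory):
        cfg = small_config()
        state = make_state(np.arange(8.0).reshape(4, 2), [1.0, 2.0, 3.0, 4.0])
        rng = forced_rng_factory(uniform_value=0.0)
        update_scouts(state, cfg, rng, indices=np.array([0]))  # fitness == best
        np.testing.assert_array_equal(state.positions[0], [0.0, 1.0])

    def test_best_at_worst_position_unmoved_for_any_k(self, forced_rng_factory):
        cfg = small_config()
        positions = np.ones((4, 2)) * 5.0
        state = make_state(positions, [1.0, 2.0, 3.0, 4.0])
        state.worst_position = positions[0].copy()  # x == xw
        rng = forced_rng_factory(uniform_value=0.9)
        update_scouts(state, cfg, rng, indices=np.array([0]))
        np.testing.assert_array_equal(state.positions[0], [5.0, 5.0])


class TestGaussianMutation:
    def test_zero_draw_is_identity(self, forced_rng_factory):
        rng = forced_rng_factory(normal_value=0.0)
        np.testing.assert_array_equal(gaussian_mutate(np.array([1.0, -2.0]), rng), [1.0, -2.0])

    def test_origin_is_fixed_for_any_draw(self, rng):
        np.testing.assert_array_equal(gaussian_mutate(np.zeros(5), rng), np.zeros(5))

    def test_half_gain(self, forced_rng_factory):
        rng = forced_rng_factory(normal_value=0.5)
        np.testing.assert_allclose(gaussian_mutate(np.array([2.0]), rng), [3.0])

    def test_single_factor_scales_all_coordinates_equally(self, rng):
        x = np.array([1.0, 2.0, -4.0])
        out = gaussian_mutate(x, rng)
        ratios = out / x
        np.testing.assert_allclose(ratios, ratios[0])


class TestRuns:
    def sphere(self, x):
        return float(np.sum(x * x))

    def test_baseline_converges_on_2d_sphere(self):
        cfg = SparrowConfig(dim=2, lower_bound=-100, upper_bound=100, pop_size=30, max_iter=500, seed=5)
        result = run_ssa(self.sphere, cfg)
        assert result.best_fitness < 1e-10

    def test_single_iteration_contract(self):
        cfg = SparrowConfig(dim=2, lower_bound=-10, upper_bound=10, pop_size=10, max_iter=1, seed=0)
        result = run_ssa(self.sphere, cfg)
        assert len(result.trace) == 1
        assert result.best_fitness <= result.trace[0] + 1e-300

    def test_fixed_seed_reproduces_baseline(self):
        cfg = SparrowConfig(dim=3, lower_bound=-5, upper_bound=5, pop_size=10, max_iter=50, seed=9)
        a, b = run_ssa(self.sphere, cfg), run_ssa(self.sphere, cfg)
        np.testing.assert_array_equal(a.trace, b.trace)
        np.testing.assert_array_equal(a.best_position, b.best_position)

    def test_fixed_seed_reproduces_improved(self):
        cfg = SparrowConfig(
            dim=3, lower_bound=-5, upper_bound=5, pop_size=10, max_iter=50,
            chaotic_map=make_map("iterative"), seed=9,
        )
        a, b = run_cgssa(self.sphere, cfg), run_cgssa(self.sphere, cfg)
        np.testing.assert_array_equal(a.trace, b.trace)

    @pytest.mark.parametrize("improved", [False, True])
    def test_trace_is_non_increasing(self, improved):
        cfg = SparrowConfig(
            dim=5, lower_bound=-10, upper_bound=10, pop_size=12, max_iter=100,
            chaotic_map=make_map("logistic") if improved else None, seed=2,
        )
        result = run_cgssa(self.sphere, cfg) if improved else run_ssa(self.sphere, cfg)
        assert np.all(np.diff(result.trace) <= 0.0)

    def test_positions_stay_inside_box(self):
        seen = []

        def spy(x):
            seen.append(x.copy())
            return self.sphere(x)

        cfg = SparrowConfig(
            dim=4, lower_bound=-1, upper_bound=1, pop_size=8, max_iter=30,
            chaotic_map=make_map("tent"), seed=3,
        )
        run_cgssa(spy, cfg)
        arr = np.array(seen)
        assert arr.min() >= -1.0 and arr.max() <= 1.0

    def test_non_finite_objective_recorded_as_inf(self):
        def bad(x):
            return np.nan if x[0] > 0 else self.sphere(x)

        cfg = SparrowConfig(dim=2, lower_bound=-10, upper_bound=10, pop_size=8, max_iter=20, seed=1)
        result = run_ssa(bad, cfg)
        assert np.isfinite(result.best_fitness)

    def test_improved_beats_baseline_in_paired_seeded_runs(self):
        # 20 paired seeds on 30-d sphere; the improved loop should win >= 15
        wins = 0
        for seed in range(1, 21):
            improved_cfg = SparrowConfig(
                dim=30, lower_bound=-100, upper_bound=100, pop_size=30, max_iter=500,
                chaotic_map=make_map("iterative"), seed=seed,
            )
            baseline_cfg = SparrowConfig(
                dim=30, lower_bound=-100, upper_bound=100, pop_size=30, max_iter=500,
                seed=seed,
            )
            f_improved = run_cgssa(self.sphere, improved_cfg).best_fitness
            f_baseline = run_ssa(self.sphere, baseline_cfg).best_fitness
            wins += f_improved <= f_baseline
        assert wins >= 15

    def test_improved_converges_deeply_on_2d_sphere(self):
        # at least 19 of 20 seeded runs reach < 1e-8
        hits = 0
        for seed in range(20):
            cfg = SparrowConfig(
                dim=2, lower_bound=-100, upper_bound=100, pop_size=30, max_iter=500,
                chaotic_map=make_map("iterative"), seed=seed,
            )
            hits += run_cgssa(self.sphere, cfg).best_fitness < 1e-8
        assert hits >= 19

    def test_wrong_runner_for_config_raises(self):
        cfg = SparrowConfig(dim=2, lower_bound=-1, upper_bound=1, pop_size=4, max_iter=5)
        with pytest.raises(ValueError):
            run_cgssa(self.sphere, cfg)
        cfg2 = SparrowConfig(
            dim=2, lower_bound=-1, upper_bound=1, pop_size=4, max_iter=5,
            chaotic_map=make_map("tent"),
        )
        with pytest.raises(ValueError):
            run_ssa(self.sphere, cfg2)


class TestConfigValidation:
    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            SparrowConfig(dim=2, lower_bound=1.0, upper_bound=-1.0)

    def test_bad_safety_threshold(self):
        with pytest.raises(ValueError):
            SparrowConfig(dim=2, lower_bound=-1, upper_bound=1, safety_threshold=0.3)

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            SparrowConfig(dim=2, lower_bound=-1, upper_bound=1, pop_size=1)
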