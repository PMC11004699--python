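"""Unit and property tests for the GOA/AGOA swarm optimizer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from goaelm.benchmarks import get_benchmark
from goaelm.optimizers import (
    BoxBounds,
    ChaoticStreams,
    OptimizerConfig,
    SearchPopulation,
    agoa_config,
    comfort_coefficient,
    goa_config,
    goa_position_update,
    opposite_point,
    optimize,
    qobl_select,
    quasi_opposite_point,
    singer_step,
    social_force,
)

CFG = OptimizerConfig()


class TestSocialForce:
    @pytest.mark.parametrize(
        "distance, expected",
        [
            (0.0, 0.5 - 1.0),                       # both exponentials are 1
            (1.0, -0.11117088165514633),            # 0.5 e^(-2/3) - e^(-1), frozen
            (500.0, 0.0),                           # kernel vanishes at range
        ],
    )
    def test_kernel_values(self, distance, expected):
        assert social_force(distance, CFG) == pytest.approx(expected, abs=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            social_force(-0.1, CFG)


class TestComfortCoefficient:
    def test_endpoints_and_midpoint(self):
        cfg = OptimizerConfig(max_iterations=100, c_max=1.0, c_min=0.01)
        assert comfort_coefficient(0, cfg) == 1.0
        assert comfort_coefficient(100, cfg) == pytest.approx(0.01)
        assert comfort_coefficient(50, cfg) == pytest.approx(0.505)

    def test_strictly_decreasing(self):
        cfg = OptimizerConfig(max_iterations=40)
        values = [comfort_coefficient(i, cfg) for i in range(41)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            comfort_coefficient(101, OptimizerConfig(max_iterations=100))


class TestSingerMap:
    def test_half_maps_to_printed_quartic_value(self):
        # raw quartic at 0.5 is inside (0,1), so no safeguard applies
        assert singer_step(0.5) == pytest.approx(0.9429375, abs=1e-12)

    def test_small_inputs_stay_small(self):
        assert 0 < singer_step(1e-9) < 1e-7

    @pytest.mark.parametrize("seed", [0.1, 0.3, 0.7])
    def test_long_orbit_stays_in_unit_interval(self, seed):
        v = seed
        for _ in range(100_000):
            v = singer_step(v)
            assert 0.0 < v < 1.0

    def test_rejects_boundary_states(self):
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                singer_step(bad)


class TestOpposition:
    def test_hand_case(self):
        bounds = BoxBounds(np.array([0.0, 0.0]), np.array([10.0, 10.0]))
        np.testing.assert_allclose(
            opposite_point(np.array([1.0, 4.0]), bounds), [9.0, 6.0]
        )

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=6))
    def test_involution(self, coords):
        x = np.asarray(coords)
        bounds = BoxBounds.cube(-5.0, 5.0, x.size)
        np.testing.assert_allclose(
            opposite_point(opposite_point(x, bounds), bounds), x, atol=1e-12
        )

    def test_center_is_fixed_point(self):
        bounds = BoxBounds.cube(-5.0, 5.0, 3)
        np.testing.assert_allclose(
            opposite_point(bounds.center, bounds), bounds.center
        )

    def test_outside_bounds_rejected(self):
        bounds = BoxBounds.cube(-5.0, 5.0, 1)
        with pytest.raises(ValueError):
            opposite_point(np.array([6.0]), bounds)


class TestQuasiOpposition:
    def test_draws_fill_center_to_opposite_interval(self, rng):
        # x = 2 in [-5, 5]: opposite is -2, center 0, so draws live in [-2, 0]
        bounds = BoxBounds.cube(-5.0, 5.0, 1)
        draws = np.array(
            [quasi_opposite_point(np.array([2.0]), bounds, rng)[0] for _ in range(10_000)]
        )
        assert np.all(draws >= -2.0) and np.all(draws <= 0.0)
        assert draws.min() < -1.98 and draws.max() > -0.02  # endpoints approached

    def test_center_degenerates_to_itself(self, rng):
        bounds = BoxBounds.cube(0.0, 10.0, 3)
        np.testing.assert_allclose(
            quasi_opposite_point(bounds.center, bounds, rng), bounds.center
        )

    def test_scalar_fraction_source(self):
        bounds = BoxBounds.cube(-5.0, 5.0, 1)
        q = quasi_opposite_point(np.array([2.0]), bounds, 0.5)
        assert q[0] == pytest.approx(-1.0)  # midpoint of [center 0, opposite -2]


class TestPositionUpdate:
    def _pop(self, positions, target, fitness=None):
        positions = np.asarray(positions, dtype=float)
        fit = np.zeros(len(positions)) if fitness is None else np.asarray(fitness)
        return SearchPopulation(positions, fit, np.asarray(target, dtype=float), 0.0)

    def test_identical_agents_stay_at_target(self):
        bounds = BoxBounds.cube(-1.0, 1.0, 2)
        t = np.array([0.3, -0.2])
        pop = self._pop([t, t], t)
        new = goa_position_update(pop, bounds, c=0.5, config=CFG)
        np.testing.assert_allclose(new, np.vstack([t, t]))

    def test_two_agent_hand_computation(self):
        # frozen from an independent arithmetic evaluation of the update sum
        bounds = BoxBounds.cube(-1.0, 1.0, 1)
        pop = self._pop([[0.2], [-0.4]], [0.1])
        new = goa_position_update(pop, bounds, c=0.5, config=CFG)
        assert new[0, 0] == pytest.approx(0.1534129032690517, abs=1e-12)
        assert new[1, 0] == pytest.approx(0.046587096730948324, abs=1e-12)

    def test_chaotic_streams_scale_social_and_target(self):
        bounds = BoxBounds.cube(-1.0, 1.0, 1)
        pop = self._pop([[0.2], [-0.4]], [0.1])
        streams = ChaoticStreams(r1=0.5, r2=0.5, r3=0.5)
        new = goa_position_update(pop, bounds, c=0.5, config=CFG, streams=streams)
        # social contribution of agent 1 was 0.0534129...; halved, target halved
        assert new[0, 0] == pytest.approx(0.5 * 0.0534129032690517 + 0.05, abs=1e-12)

    def test_output_clamped_into_bounds(self, rng):
        bounds = BoxBounds.cube(-2.0, 2.0, 3)
        X = rng.uniform(-2, 2, size=(8, 3))
        pop = self._pop(X, X[0])
        new = goa_position_update(pop, bounds, c=1.0, config=CFG)
        assert np.all(new >= bounds.lower) and np.all(new <= bounds.upper)


class TestQoblSelect:
    def test_lower_fitness_wins_and_ties_keep_candidate(self):
        a = (np.array([1.0]), 3.0)
        b = (np.array([2.0]), 5.0)
        assert qobl_select(a, b) is a
        assert qobl_select(b, a) is a
        tie = (np.array([9.0]), 3.0)
        assert qobl_select(a, tie) is a


class TestOptimize:
    def test_constant_objective_resolved_immediately(self):
        bounds = BoxBounds.cube(-1.0, 1.0, 2)
        res = optimize(lambda x: 7.25, bounds, goa_config(population_size=5, max_iterations=3))
        assert res.best_fitness == 7.25
        assert res.convergence_history[0] == 7.25

    def test_same_seed_bit_identical(self):
        f1 = get_benchmark("F1", 3)
        cfg = agoa_config(population_size=10, max_iterations=15, rng_seed=42)
        r1 = optimize(f1, f1.bounds, cfg)
        r2 = optimize(f1, f1.bounds, cfg)
        np.testing.assert_array_equal(r1.convergence_history, r2.convergence_history)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)

    @pytest.mark.parametrize("factory", [goa_config, agoa_config])
    def test_history_non_increasing_and_consistent(self, factory):
        f3 = get_benchmark("F3", 4)
        res = optimize(f3, f3.bounds, factory(population_size=12, max_iterations=25, rng_seed=5))
        h = res.convergence_history
        assert h.size == 26
        assert np.all(np.diff(h) <= 0)
        assert res.best_fitness == h[-1]
        assert f3.bounds.contains(res.best_position)

    def test_non_finite_objective_recorded_as_inf(self):
        bounds = BoxBounds.cube(-1.0, 1.0, 1)

        def spiky(x):
            return float("nan") if x[0] > 0 else float(x[0] ** 2)

        res = optimize(spiky, bounds, goa_config(population_size=6, max_iterations=5, rng_seed=0))
        assert math.isfinite(res.best_fitness)

    def test_agoa_reaches_sphere_optimum(self):
        # amended variant should solve the 2-D sphere to 1e-6 in almost all seeds
        f1 = get_benchmark("F1", 2)
        hits = sum(
            optimize(f1, f1.bounds, agoa_config(rng_seed=s)).best_fitness <= 1e-6
            for s in range(20)
        )
        assert hits >= 18

    def test_qobl_counts_extra_evaluations(self):
        f1 = get_benchmark("F1", 2)
        plain = optimize(f1, f1.bounds, goa_config(population_size=8, max_iterations=10, rng_seed=1))
        amended = optimize(f1, f1.bounds, agoa_config(population_size=8, max_iterations=10, rng_seed=1))
        assert plain.evaluations_used == 8 + 8 * 10
        assert amended.evaluations_used == 8 + 2 * 8 * 10
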