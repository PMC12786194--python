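"""Swarm optimizer dynamics, budgets, determinism and oracle convergence."""

import numpy as np
import pytest

from swarmthresh import (
    HybridConfig,
    Population,
    ThresholdSet,
    brute_force_thresholds,
    evaluate_thresholds,
    run_baseline,
    run_scsowoa,
    scso_step,
    woa_step,
)
from conftest import random_histogram


class _ScriptedRng:
    """Feeds predetermined draws to a step function, in call order."""

    def __init__(self, draws):
        self._draws = list(draws)

    def _next(self, size):
        out = np.asarray(self._draws.pop(0), dtype=float)
        assert out.shape == (size,)
        return out

    def random(self, size):
        return self._next(size)

    def uniform(self, lo, hi, size):
        return self._next(size)

    def integers(self, lo, hi, size):
        return self._next(size).astype(np.int64)


def _make_pop(positions, best, hist, rng):
    positions = np.asarray(positions, dtype=float)
    pop = Population(
        positions=positions,
        fitness=np.zeros(len(positions)),
        best_position=np.asarray(best, dtype=float),
        best_fitness=-np.inf,
        rng=rng,
        objective=lambda p: evaluate_thresholds(hist, p),
        bounds=(1.0, float(hist.n_levels - 1)),
    )
    pop.best_fitness = float(pop.evaluate(pop.best_position[None, :])[0])
    pop.n_evals = 0
    return pop


@pytest.fixture
def small_hist(rng):
    return random_histogram(rng)


class TestScsoStep:
    def test_hunt_branch_zero_coefficients_is_identity(self, small_hist):
        """X + r1*X* - r2*X with r1 = r2 = 0 leaves positions unchanged."""
        rng = _ScriptedRng([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [0.5, 0.5]])
        pop = _make_pop([[40.0, 90.0], [120.0, 200.0]], [60.0, 130.0], small_hist, rng)
        before = pop.positions.copy()
        scso_step(pop, HybridConfig(), t=1)
        np.testing.assert_array_equal(pop.positions, before)

    def test_attraction_branch_full_step_reaches_best(self, small_hist):
        """X + r3*(X* - X) with r3 = 1 lands exactly on the best."""
        rng = _ScriptedRng([[0.9, 0.9], [0.5, 0.5], [0.5, 0.5], [1.0, 1.0]])
        pop = _make_pop([[40.0, 90.0], [120.0, 200.0]], [60.0, 130.0], small_hist, rng)
        scso_step(pop, HybridConfig(), t=1)
        np.testing.assert_allclose(pop.positions, [[60.0, 130.0]] * 2)

    def test_replay_from_logged_draws(self, small_hist):
        """One logged step reproduces by hand-applying the chosen equation."""
        pop = _make_pop(
            [[40.0, 90.0], [120.0, 200.0]],
            [60.0, 130.0],
            small_hist,
            np.random.default_rng(7),
        )
        before = pop.positions.copy()
        best = pop.best_position.copy()
        scso_step(pop, HybridConfig(log_draws=True), t=1)
        log = pop.draw_log[-1]
        for i in range(2):
            if log["coin"][i] < 0.5:
                expect = before[i] + log["r1"][i] * best - log["r2"][i] * before[i]
            else:
                expect = before[i] + log["r3"][i] * (best - before[i])
            np.testing.assert_allclose(
                pop.positions[i], np.clip(expect, 1.0, 255.0)
            )

    def test_mean_attraction_mode(self, small_hist):
        """The alternative single-rule update pulls toward mean and best."""
        rng = _ScriptedRng([[0.5, 0.5], [0.25, 0.25]])
        pop = _make_pop([[40.0, 90.0], [120.0, 200.0]], [60.0, 130.0], small_hist, rng)
        before = pop.positions.copy()
        mean = before.mean(axis=0)
        scso_step(pop, HybridConfig(scso_update_mode="mean_attraction"), t=1)
        expect = before + 0.5 * (mean - before) + 0.25 * (
            np.array([60.0, 130.0]) - before
        )
        np.testing.assert_allclose(pop.positions, np.clip(expect, 1.0, 255.0))


class TestWoaStep:
    def test_encircle_with_zero_A_reaches_best(self, small_hist):
        # p < 0.5 selects the A-branch; r_a = 0.5 makes A = 0 for any a
        rng = _ScriptedRng(
            [[0.1, 0.1], [0.5, 0.5], [0.3, 0.3], [0.0, 0.0], [0.0, 1.0]]
        )
        pop = _make_pop([[40.0, 90.0], [120.0, 200.0]], [60.0, 130.0], small_hist, rng)
        woa_step(pop, HybridConfig(), t=1, t_phase=40)
        np.testing.assert_allclose(pop.positions, [[60.0, 130.0]] * 2)

    def test_spiral_at_best_stays_at_best(self, small_hist):
        """D' = 0 collapses the spiral onto X* for any l."""
        rng = _ScriptedRng(
            [[0.9, 0.9], [0.5, 0.5], [0.3, 0.3], [0.7, -0.4], [0.0, 1.0]]
        )
        pop = _make_pop([[60.0, 130.0], [60.0, 130.0]], [60.0, 130.0], small_hist, rng)
        woa_step(pop, HybridConfig(), t=1, t_phase=40)
        np.testing.assert_allclose(pop.positions, [[60.0, 130.0]] * 2)

    def test_a_schedule_linear_endpoints(self, small_hist):
        cfg = HybridConfig(log_draws=True)
        for t, expect in ((20, 1.0), (40, 0.0)):
            pop = _make_pop(
                [[40.0, 90.0], [120.0, 200.0]],
                [60.0, 130.0],
                small_hist,
                np.random.default_rng(0),
            )
            woa_step(pop, cfg, t=t, t_phase=40)
            assert pop.draw_log[-1]["a"] == pytest.approx(expect)

    def test_pseudocode_mode_search_branch(self, small_hist):
        """|A| >= 1 moves relative to a random agent, not the best."""
        # single r drives both A and C: r = 0 gives A = -a, C = 0
        rng = _ScriptedRng([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        pop = _make_pop([[40.0, 90.0], [120.0, 200.0]], [60.0, 130.0], small_hist, rng)
        before = pop.positions.copy()
        woa_step(pop, HybridConfig(woa_branch_mode="pseudocode"), t=1, t_phase=40)
        # y_i = y_rand - A*|C*y_rand - y_i| with A = -a = -2*(1 - 1/40), C = 0
        a = 2.0 * (1.0 - 1.0 / 40.0)
        expect0 = before[1] + a * np.abs(-before[0])
        np.testing.assert_allclose(pop.positions[0], np.clip(expect0, 1.0, 255.0))

    def test_empty_phase_rejected(self, small_hist):
        pop = _make_pop([[40.0, 90.0]], [60.0, 130.0], small_hist, None)
        with pytest.raises(ValueError):
            woa_step(pop, HybridConfig(), t=1, t_phase=0)


class TestHybridRun:
    def test_phase_split_default(self):
        assert HybridConfig().phase_split() == (60, 40)

    @pytest.mark.parametrize(
        "ratio,expect", [(0.0, (0, 100)), (1.0, (100, 0)), (0.35, (35, 65))]
    )
    def test_phase_split_general(self, ratio, expect):
        assert HybridConfig(switch_ratio=ratio).phase_split() == expect

    def test_two_point_plateau_found(self, two_point_hist):
        ts, j, trace = run_scsowoa(two_point_hist, 1, HybridConfig(rng_seed=11))
        assert j == pytest.approx(5625.0)
        assert len(trace.best_fitness) == 100
        assert trace.phase[:60] == ["scso"] * 60
        assert trace.phase[60:] == ["woa"] * 40

    def test_evaluation_budget_exact(self, two_point_hist):
        for ratio in (0.6, 1.0):
            cfg = HybridConfig(switch_ratio=ratio, rng_seed=1)
            _, _, trace = run_scsowoa(two_point_hist, 2, cfg)
            assert trace.total_evaluations == 30 * 101

    def test_pure_woa_ratio_budget(self, two_point_hist):
        """lambda = 0: one random best draw replaces the exploration phase."""
        _, _, trace = run_scsowoa(two_point_hist, 2, HybridConfig(switch_ratio=0.0))
        assert trace.total_evaluations == 1 + 30 * 100

    def test_elitism_across_handoff(self, suite_histograms):
        for hist in suite_histograms.values():
            _, _, trace = run_scsowoa(hist, 4, HybridConfig(rng_seed=5))
            diffs = np.diff(trace.best_fitness)
            assert np.all(diffs >= 0.0)

    def test_determinism_bit_identical(self, suite_histograms):
        hist = suite_histograms["trimodal"]
        cfg = HybridConfig(rng_seed=123)
        a = run_scsowoa(hist, 3, cfg)
        b = run_scsowoa(hist, 3, cfg)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        assert a[1] == b[1]
        assert a[2].best_fitness == b[2].best_fitness

    def test_bounds_respected(self, suite_histograms):
        hist = suite_histograms["fivemode"]
        ts, _, _ = run_scsowoa(hist, 6, HybridConfig(rng_seed=2))
        assert np.all(ts.values >= 1.0) and np.all(ts.values <= 255.0)

    def test_oracle_convergence_small_instance(self, suite_histograms):
        """Median-over-seeds best J reaches 99.5% of the exhaustive optimum."""
        hist = suite_histograms["trimodal"]
        _, j_star = brute_force_thresholds(hist, 2)
        js = [
            run_scsowoa(hist, 2, HybridConfig(rng_seed=s))[1] for s in range(10)
        ]
        assert np.median(js) >= 0.995 * j_star


class TestBaselines:
    def test_all_reach_two_point_optimum(self, two_point_hist):
        for name in ("pso", "gwo", "woa", "scso"):
            _, j, trace = run_baseline(name, two_point_hist, 1, HybridConfig(rng_seed=0))
            assert j == pytest.approx(5625.0), name
            assert trace.total_evaluations == 30 * 101, name

    def test_pso_null_dynamics_freezes_population(self, two_point_hist):
        """w = c1 = c2 = 0 keeps the initialization best forever."""
        cfg = HybridConfig(
            pso_inertia=0.0, pso_cognitive=0.0, pso_social=0.0,
            total_iterations=20, rng_seed=4,
        )
        _, j, trace = run_baseline("pso", two_point_hist, 1, cfg)
        assert len(set(trace.best_fitness)) == 1
        assert j == trace.best_fitness[0]

    def test_gwo_zero_a_averages_leaders(self, small_hist):
        """At a = 0 every wolf lands on the mean of the three leaders."""
        from swarmthresh.optimizers import _gwo, HybridConfig as HC

        pop = _make_pop(
            np.random.default_rng(1).uniform(1, 255, (5, 2)),
            [60.0, 130.0],
            small_hist,
            np.random.default_rng(2),
        )
        pop.fitness = np.atleast_1d(pop.objective(pop.positions))
        order = np.argsort(pop.fitness)[::-1]
        expect = pop.positions[order[:3]].mean(axis=0)
        _gwo(pop, HC(total_iterations=10), t=10)  # a = a0*(1 - 10/10) = 0
        np.testing.assert_allclose(pop.positions, np.tile(expect, (5, 1)))

    def test_unknown_name_rejected(self, two_point_hist):
        with pytest.raises(ValueError, match="unknown"):
            run_baseline("cuckoo", two_point_hist, 1, HybridConfig())

    def test_baseline_determinism(self, suite_histograms):
        hist = suite_histograms["bimodal"]
        for name in ("pso", "gwo", "woa", "scso"):
            a = run_baseline(name, hist, 2, HybridConfig(rng_seed=9))
            b = run_baseline(name, hist, 2, HybridConfig(rng_seed=9))
            np.testing.assert_array_equal(a[0].values, b[0].values)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"population_size": 1},
            {"total_iterations": 0},
            {"switch_ratio": 1.5},
            {"scso_update_mode": "bogus"},
            {"woa_branch_mode": "bogus"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HybridConfig(**kwargs)
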