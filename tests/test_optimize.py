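"""Gradient correctness, Adam fitting, curriculum and checkpointing."""

import numpy as np
import pytest

import tfcircuit as tc
from tfcircuit.objective import LossSpec, grid_times, transform_y
from tfcircuit.optimize import (
    FitProblem,
    OptimizerConfig,
    circadian_problem,
    curriculum_windows,
    evaluate_gradient,
    fit,
)
from tfcircuit.params import VectorLayout


def recovery_problem(n, params_true, window, sim_dt):
    """Fit target = the transformed TF-1 trajectory of a known circuit."""
    traj = tc.simulate_path(params_true, window, dt=sim_dt, save_dt=0.02)
    target = transform_y(traj.y[:-1, 0])  # half-open grid

    def target_fn(times):
        idx = np.round(times / 0.02).astype(int)
        return target[idx]

    return FitProblem(n=n, target_fn=target_fn)


class TestCurriculum:
    def test_geometric_doubling(self):
        assert curriculum_windows(4.0, 3) == [1.0, 2.0, 4.0]

    def test_single_stage(self):
        assert curriculum_windows(5.0, 1) == [5.0]

    def test_ascending_ending_at_t_end(self):
        w = curriculum_windows(6.0, 4)
        assert w == sorted(w) and w[-1] == 6.0


class TestGradient:
    def test_matches_central_differences(self, rng):
        """Adjoint gradient vs central FD on every coordinate of a 1-gene
        circadian problem (unbounded scale, step 1e-4)."""
        problem = circadian_problem(1)
        config = OptimizerConfig(sim_dt=2e-3, t_end=1.0)
        v = tc.encode(tc.init_params(1, rng, 0.2))
        _, g = evaluate_gradient(v, problem, config, window=1.0)
        for i in range(len(v)):
            e = np.zeros_like(v)
            e[i] = 1e-4
            lp, _ = evaluate_gradient(v + e, problem, config, window=1.0)
            lm, _ = evaluate_gradient(v - e, problem, config, window=1.0)
            fd = (lp - lm) / 2e-4
            assert fd == pytest.approx(g[i], rel=1e-3, abs=1e-10)

    def test_stationary_at_generating_parameters(self, rng):
        """Target generated from v itself: loss 0, gradient ~0."""
        n = 2
        params = tc.init_params(n, rng, 0.2)
        problem = recovery_problem(n, params, 1.0, 2e-3)
        config = OptimizerConfig(sim_dt=2e-3, t_end=1.0)
        v = tc.encode(params)
        loss, g = evaluate_gradient(v, problem, config, window=1.0)
        assert loss < 1e-12
        assert np.linalg.norm(g) < 1e-6

    def test_stochastic_gradient_repeatable(self, rng):
        problem = circadian_problem(2, drive=tc.DriveSpec(), light_w=2.0)
        config = OptimizerConfig(
            mode="stochastic", noise_realizations=2, sim_dt=2e-3, t_end=0.5
        )
        v = tc.encode(tc.init_params(2, rng, 0.1))
        out = [
            evaluate_gradient(v, problem, config, 0.5, np.random.default_rng(9))
            for _ in range(2)
        ]
        assert out[0][0] == out[1][0]
        assert np.array_equal(out[0][1], out[1][1])

    def test_stochastic_requires_rng(self, rng):
        problem = circadian_problem(1)
        config = OptimizerConfig(mode="stochastic", t_end=0.5)
        v = tc.encode(tc.init_params(1, rng, 0.1))
        with pytest.raises(ValueError):
            evaluate_gradient(v, problem, config, 0.5, None)


class TestFit:
    def test_zero_iterations_echoes_start(self, rng):
        problem = circadian_problem(1)
        config = OptimizerConfig(max_iters=0, t_end=0.5, n_stages=1, sim_dt=2e-3)
        v0 = tc.encode(tc.init_params(1, rng, 0.1))
        res = fit(v0, config, problem)
        assert np.array_equal(res.v, v0)
        assert len(res.loss_history) == 1

    def test_same_seed_identical_history(self, rng):
        problem = circadian_problem(1)
        config = OptimizerConfig(
            max_iters=5, t_end=0.5, n_stages=1, sim_dt=2e-3, seed=4
        )
        v0 = tc.encode(tc.init_params(1, rng, 0.1))
        h1 = fit(v0, config, problem).history_frame()
        h2 = fit(v0, config, problem).history_frame()
        assert h1["loss"].tolist() == h2["loss"].tolist()

    def test_constant_target_quadratic_sanity(self, rng):
        """One gene driven to hold a constant transformed level: the loss
        collapses below 1e-8 within 2000 Adam steps."""
        problem = FitProblem(n=1, target_fn=lambda t: np.full(len(t), 0.3))
        config = OptimizerConfig(
            learning_rate=0.02, max_iters=2000, t_end=1.0, n_stages=1,
            sim_dt=0.01, stop_loss=1e-9,
        )
        v0 = tc.encode(tc.init_params(1, rng, 0.1))
        res = fit(v0, config, problem)
        assert res.best_loss < 1e-8

    def test_best_loss_nonincreasing(self, rng):
        problem = circadian_problem(2)
        config = OptimizerConfig(max_iters=40, t_end=1.0, n_stages=2, sim_dt=5e-3)
        v0 = tc.encode(tc.init_params(2, rng, 0.1))
        res = fit(v0, config, problem)
        h = res.history_frame()
        final = h[h.stage == h.stage.max()]["loss"]
        assert res.best_loss <= final.min() + 1e-15

    def test_trajectory_recovery_two_genes(self, rng):
        """Data generated from known parameters, fit from a 10%-perturbed
        start: the fitted trajectory reconverges even if raw parameters
        differ (trajectory match, not identifiability)."""
        n = 2
        true = tc.init_params(n, np.random.default_rng(0), 0.0)
        problem = recovery_problem(n, true, 1.0, 2e-3)
        start = tc.init_params(n, np.random.default_rng(1), 0.1)
        config = OptimizerConfig(
            max_iters=400, t_end=1.0, n_stages=1, sim_dt=2e-3, stop_loss=1e-4
        )
        res = fit(tc.encode(start), config, problem)
        init_loss = res.history_frame()["loss"].iloc[0]
        assert res.best_loss < 0.05 * init_loss
        # per-grid-point transformed deviation
        n_grid = int(round(1.0 / 0.02))
        assert np.sqrt(res.best_loss / n_grid) < 0.05

    def test_nan_target_triggers_failure_policy(self, rng):
        problem = FitProblem(n=1, target_fn=lambda t: np.full(len(t), np.nan))
        config = OptimizerConfig(
            max_iters=20, t_end=0.5, n_stages=1, sim_dt=5e-3, max_failures=3
        )
        v0 = tc.encode(tc.init_params(1, rng, 0.1))
        with pytest.raises(RuntimeError, match="non-finite"):
            fit(v0, config, problem)

    def test_wrong_length_v0(self):
        with pytest.raises(ValueError):
            fit(np.zeros(5), OptimizerConfig(), circadian_problem(2))


class TestConfigValidation:
    def test_bad_mode(self):
        with pytest.raises(ValueError):
            OptimizerConfig(mode="annealing")

    def test_bad_rate(self):
        with pytest.raises(ValueError):
            OptimizerConfig(learning_rate=0.0)

    def test_non_ascending_curriculum(self):
        with pytest.raises(ValueError):
            OptimizerConfig(curriculum=(2.0, 1.0))


def test_fit_result_save_round_trip(tmp_path, rng):
    problem = circadian_problem(1)
    config = OptimizerConfig(max_iters=2, t_end=0.5, n_stages=1, sim_dt=5e-3)
    res = fit(tc.encode(tc.init_params(1, rng, 0.1)), config, problem)
    res.save(tmp_path)
    assert (tmp_path / "params.json").exists()
    assert (tmp_path / "manifest.json").exists()
    p = tc.ModelParams.from_json(tmp_path / "params.json")
    assert p.n == 1
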