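"""Integrators, noise model and the telegraph light signal."""

import numpy as np
import pytest

import tfcircuit as tc
from tfcircuit.dynamics import (
    SECONDS_PER_DAY,
    noise_amplitude_grad,
    _exp_factors,
)


def closed_form(params, c, times):
    """Exact solution of the constant-activation single-gene system."""
    m = params.m[0] * SECONDS_PER_DAY
    d = params.delta[0] * SECONDS_PER_DAY
    s = params.s[0] * SECONDS_PER_DAY
    g = params.gamma[0] * SECONDS_PER_DAY
    xeq = m * c / d
    x = xeq + (params.x0[0] - xeq) * np.exp(-d * times)
    # y' = s x - g y, linear; solve with variation of constants
    yeq = s * xeq / g
    a = s * (params.x0[0] - xeq) / (g - d)
    y = yeq + a * np.exp(-d * times) + (params.y0[0] - yeq - a) * np.exp(-g * times)
    return x, y


class TestOdeRhs:
    def test_absorbing_origin(self, rng):
        p = tc.init_params(2, rng, 0.0)
        p.alpha[:] = 0.0
        state = np.zeros(4)
        assert np.allclose(tc.ode_rhs(state, 0.0, p), 0.0)

    def test_fixed_point_of_constant_activation(self, constant_f_gene):
        p, c = constant_f_gene
        m, d = p.m[0] * SECONDS_PER_DAY, p.delta[0] * SECONDS_PER_DAY
        s, g = p.s[0] * SECONDS_PER_DAY, p.gamma[0] * SECONDS_PER_DAY
        xstar = m * c / d
        ystar = s * xstar / g
        rhs = tc.ode_rhs(np.array([xstar, ystar]), 0.0, p)
        assert np.allclose(rhs, 0.0, atol=1e-8 * max(xstar, ystar))

    def test_drive_nullity(self, params2):
        state = np.array([1.0, 2.0, 300.0, 400.0])
        no_drive = tc.ode_rhs(state, 0.6, params2)
        zero_gain = tc.ode_rhs(
            state, 0.6, params2,
            schedule=tc.LightSchedule(np.array([0.1])),
            drive=tc.DriveSpec(gain=0.0),
        )
        assert np.array_equal(no_drive, zero_gain)


class TestSimulateOde:
    def test_matches_closed_form(self, constant_f_gene):
        p, c = constant_f_gene
        traj = tc.simulate_ode(p, 5.0, rtol=1e-10, atol=1e-10)
        x, y = closed_form(p, c, traj.times)
        assert np.max(np.abs(traj.x[:, 0] - x) / np.maximum(np.abs(x), 1)) < 1e-6
        assert np.max(np.abs(traj.y[:, 0] - y) / np.maximum(np.abs(y), 1)) < 1e-6

    def test_zero_production_stays_zero(self, rng):
        p = tc.init_params(1, rng, 0.0)
        p.m[:] = 1e-4  # lower bound; also kill activation and ICs
        p.alpha[:] = 0.0
        p.x0[:] = 0.0
        p.y0[:] = 0.0
        traj = tc.simulate_ode(p, 1.0)
        assert np.allclose(traj.x, 0.0, atol=1e-9)
        assert np.allclose(traj.y, 0.0, atol=1e-9)

    def test_tolerance_convergence(self, params2):
        a = tc.simulate_ode(params2, 2.0, rtol=1e-8, atol=1e-8)
        b = tc.simulate_ode(params2, 2.0, rtol=1e-10, atol=1e-10)
        rel = np.abs(a.y[-1] - b.y[-1]) / np.maximum(np.abs(b.y[-1]), 1)
        assert np.max(rel) < 1e-6

    def test_mrna_ceiling(self, rng):
        """With f <= 1, mRNA can never exceed max(x0, m/delta) <= 100."""
        for seed in range(20):
            p = tc.init_params(3, np.random.default_rng(seed), 0.4)
            traj = tc.simulate_ode(p, 2.0)
            ceiling = np.maximum(p.x0, p.m / p.delta)
            assert np.all(traj.x <= ceiling[None, :] * (1 + 1e-6))
            assert np.all(traj.x <= 100 * (1 + 1e-6))


class TestNoiseAmplitude:
    def test_sqrt_branch(self):
        assert tc.noise_amplitude(100.0) == pytest.approx(10.0)

    def test_branches_agree_at_16(self):
        assert tc.noise_amplitude(16.0) == 4.0
        assert tc.noise_amplitude(np.nextafter(16.0, 17)) == pytest.approx(4.0, rel=1e-7)

    def test_zero(self):
        assert tc.noise_amplitude(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tc.noise_amplitude(-1.0)

    def test_grad_branches(self):
        assert noise_amplitude_grad(4.0) == 0.25
        assert noise_amplitude_grad(100.0) == pytest.approx(0.05)


class TestSde:
    def test_zero_noise_matches_ode_endpoint(self, constant_f_gene):
        p, c = constant_f_gene
        ode = tc.simulate_ode(p, 2.0, rtol=1e-10, atol=1e-10)
        path = tc.simulate_path(p, 2.0, dt=1e-3, save_dt=0.02)
        rel = np.abs(path.y[-1] - ode.y[-1]) / np.abs(ode.y[-1])
        assert rel.max() < 1e-3

    def test_zero_noise_nonlinear_system(self, params2):
        ode = tc.simulate_ode(params2, 1.0, rtol=1e-10, atol=1e-10)
        path = tc.simulate_path(params2, 1.0, dt=1e-3, save_dt=0.02)
        rel = np.abs(path.y[-1] - ode.y[-1]) / np.maximum(np.abs(ode.y[-1]), 1)
        assert rel.max() < 1e-3

    def test_seed_determinism(self, params2):
        a = tc.simulate_sde(params2, 1.0, 1e-3, np.random.default_rng(11))
        b = tc.simulate_sde(params2, 1.0, 1e-3, np.random.default_rng(11))
        assert np.array_equal(a.y, b.y) and np.array_equal(a.x, b.x)

    def test_trajectories_never_negative(self, rng):
        for seed in range(20):
            p = tc.init_params(2, np.random.default_rng(seed), 0.3)
            p.x0[:] = 0.5  # start near zero so the floor is exercised
            traj = tc.simulate_sde(p, 0.5, 1e-3, np.random.default_rng(seed + 100))
            assert np.all(traj.x >= 0) and np.all(traj.y >= 0)

    def test_pure_noise_variance(self):
        """Rates ~0: per-step increments are Gaussian with variance
        amp(z)**2 * dt = z * dt for z >> 16."""
        z0 = 1e4
        p = tc.ModelParams(
            n=1, m=np.zeros(1), delta=np.zeros(1), s=np.zeros(1), gamma=np.zeros(1),
            x0=np.array([z0]), y0=np.array([z0]), k=np.array([[5e2]]),
            h=np.array([[2.0]]), alpha=np.zeros((1, 2)), r=np.ones((1, 0)),
        )
        dt = 1e-4
        traj = tc.simulate_sde(p, 1.0, dt, np.random.default_rng(0))
        inc = np.diff(traj.y[:, 0])
        assert len(inc) == 10_000
        assert np.var(inc) == pytest.approx(z0 * dt, rel=0.05)

    def test_light_nullity(self, params2):
        """An always-off schedule is bit-identical to zero drive gain."""
        empty = tc.LightSchedule(np.empty(0))
        a = tc.simulate_sde(
            params2, 0.5, 1e-3, np.random.default_rng(3),
            schedule=empty, drive=tc.DriveSpec(),
        )
        b = tc.simulate_sde(
            params2, 0.5, 1e-3, np.random.default_rng(3),
            schedule=empty, drive=tc.DriveSpec(gain=0.0),
        )
        assert np.array_equal(a.y, b.y)

    def test_bad_dt_raises(self, params2):
        with pytest.raises(ValueError):
            tc.simulate_path(params2, 1.0, dt=0.03, save_dt=0.02)


class TestExpFactors:
    def test_limits(self):
        E, phi = _exp_factors(np.array([0.0]), 1e-3)
        assert E[0] == 1.0 and phi[0] == pytest.approx(1e-3)
        E, phi = _exp_factors(np.array([2.0]), 0.5)
        assert E[0] == pytest.approx(np.exp(-1.0))
        assert phi[0] == pytest.approx((1 - np.exp(-1.0)) / 2.0)


class TestLightSchedule:
    def test_initially_off(self, rng):
        for _ in range(50):
            s = tc.sample_light_schedule(2.0, 20.0, rng)
            assert s.state_at(0.0) == False  # noqa: E712

    def test_state_parity(self):
        s = tc.LightSchedule(np.array([1.0, 3.0, 4.0]))
        assert s.state_at(np.array([0.5, 2.0, 3.5, 10.0])).tolist() == [
            False, True, False, True,
        ]

    def test_switch_count_poisson_mean(self):
        """At w=2 over 20 days, switches per schedule average 20/2 = 10."""
        rng = np.random.default_rng(123)
        counts = np.array(
            [len(tc.sample_light_schedule(2.0, 20.0, rng).switch_times) for _ in range(10_000)]
        )
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 10.0) < 3 * se

    def test_rare_switching_tail(self):
        """w=1000, 20 days: P(no switch) = exp(-0.02) ~ 0.98."""
        rng = np.random.default_rng(7)
        none = np.mean(
            [len(tc.sample_light_schedule(1000.0, 20.0, rng).switch_times) == 0
             for _ in range(10_000)]
        )
        assert none == pytest.approx(np.exp(-0.02), abs=0.01)

    def test_non_ascending_rejected(self):
        with pytest.raises(ValueError):
            tc.LightSchedule(np.array([2.0, 1.0]))

    def test_invalid_wait(self, rng):
        with pytest.raises(ValueError):
            tc.sample_light_schedule(0.0, 10.0, rng)
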