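"""Neuron models: analytic moment surfaces vs stochastic simulation."""

import math
from dataclasses import replace

import numpy as np
import pytest

import dualhomeo as dh
from dualhomeo.neuron_models import (NonStationaryInputError, StepSizeError,
                                     filtered_input_constant_quadrature,
                                     sample_input)


def empirical(trace, discard=0.1):
    t = trace[int(len(trace) * discard):]
    return float(np.mean(t)), float(np.var(t))


class TestFilteredInputConstant:
    def test_white_gives_sigma_squared(self):
        inp = dh.StationaryInput(kind="white", sigma=0.5)
        assert dh.filtered_input_constant(inp, 0.1) == 0.25

    def test_constant_gives_zero(self):
        assert dh.filtered_input_constant(dh.StationaryInput(), 0.1) == 0.0

    def test_ou_closed_form_matches_quadrature(self):
        inp = dh.StationaryInput(kind="ou_correlated", sigma_I=0.3, tau_I=2.0)
        C = dh.filtered_input_constant(inp, 0.5)
        assert C == pytest.approx(2 * 0.5 * 0.09 * 2.0 / 2.5, rel=1e-12)
        assert C == pytest.approx(
            filtered_input_constant_quadrature(inp, 0.5), rel=1e-4)

    def test_ou_variance_against_simulation(self):
        """g^2 sigma_I^2 tau_I/(tau_I + tau_r): long run of the rate SDE
        driven by an exactly discretized OU input."""
        inp = dh.StationaryInput(kind="ou_correlated", phi=1.0,
                                 sigma_I=0.3, tau_I=2.0)
        unit = dh.OURateUnit(tau_r=0.5, input=inp)
        g = 2.0
        _, r = dh.simulate_fast(unit, dh.ControlState(0.0, g),
                                T=4000.0, dt=0.002, seed=11)
        expected = g**2 * 0.09 * 2.0 / 2.5
        _, var = empirical(r)
        assert var == pytest.approx(expected, rel=0.15)

    def test_pulses_not_stationary(self):
        inp = dh.StationaryInput(kind="pulses", pulse_amplitude=1.0,
                                 pulse_width=0.1, pulse_interval=1.0,
                                 n_pulses=3)
        with pytest.raises(NonStationaryInputError):
            dh.filtered_input_constant(inp, 0.1)


class TestOUSurface:
    def test_closed_form_values(self):
        unit = dh.OURateUnit(tau_r=0.5, eta=1.0,
                             input=dh.StationaryInput(kind="constant", phi=2.0))
        s = dh.ou_moment_surface(unit)
        assert s.mu(1.0, 0.0) == 1.0                     # g = 0: mu = x
        assert s.nu(1.0, 0.0) == pytest.approx(1.0)      # eta^2/(2 tau_r)
        assert s.mu(0.5, 1.0) == pytest.approx(2.5)      # g phi + x

    def test_white_noise_variance_against_simulation(self):
        unit = dh.OURateUnit(tau_r=0.5,
                             input=dh.StationaryInput(kind="white", phi=1.0,
                                                      sigma=0.5))
        s = dh.ou_moment_surface(unit)
        x, g = 0.0, 2.0
        _, r = dh.simulate_fast(unit, dh.ControlState(x, g), T=3000.0,
                                dt=0.002, seed=2)
        mean, var = empirical(r)
        # 3 standard errors for the mean; generous band for the variance
        se = math.sqrt(2 * s.nu(x, g) * 0.5 / 3000.0)
        assert abs(mean - s.mu(x, g)) < 3 * se
        assert var == pytest.approx(s.nu(x, g), rel=0.1)
        assert s.nu(x, g) == pytest.approx(g**2 * 0.25 / 1.0)


class TestPoissonCalciumSurface:
    def test_shot_noise_floor_exact_at_zero_gain(self):
        unit = dh.PoissonCalciumUnit(delta=0.5, tau_d=2.0)
        s = dh.poisson_calcium_moment_surface(unit)
        mu, nu = s.mu(3.0, 0.0), s.nu(3.0, 0.0)
        assert nu == pytest.approx(0.5 * unit.delta * mu, rel=1e-12)
        assert s.nu_floor(mu) == pytest.approx(nu, rel=1e-12)

    def test_determinant_factor(self):
        inp = dh.StationaryInput(kind="ou_correlated", phi=1.0,
                                 sigma_I=0.5, tau_I=5.0)
        unit = dh.PoissonCalciumUnit(delta=1.0, tau_d=2.0, input=inp)
        C = dh.filtered_input_constant(inp, unit.tau_d)
        s = dh.poisson_calcium_moment_surface(unit)
        for g in (0.5, 1.0, 2.0):
            p = s.at(1.0, g)
            det = p.moment_jacobian_det()
            assert det == pytest.approx(
                2 * unit.delta**3 * unit.tau_d**2 * C * g, rel=1e-10)
            assert det > 0

    def test_sensor_moments_against_shot_noise_simulation(self):
        # delta=1, tau_d=2, constant input phi=1, g=1, x=0: mu=2, nu=1
        unit = dh.PoissonCalciumUnit(delta=1.0, tau_d=2.0)
        s = dh.poisson_calcium_moment_surface(unit)
        assert (s.mu(0.0, 1.0), s.nu(0.0, 1.0)) == (2.0, 1.0)
        _, rho = dh.simulate_fast(unit, dh.ControlState(0.0, 1.0),
                                  T=6000.0, dt=0.005, seed=4)
        mean, var = empirical(rho)
        assert mean == pytest.approx(2.0, abs=0.1)
        assert var == pytest.approx(1.0, rel=0.15)

    def test_nonpositive_rate_outside_domain(self):
        unit = dh.PoissonCalciumUnit()
        s = dh.poisson_calcium_moment_surface(unit)
        with pytest.raises(ValueError):
            s.at(-2.0, 1.0)


class TestRecurrentSurface:
    def test_closed_form_values(self):
        unit = dh.SelfExcitatoryUnit(
            eta=math.sqrt(5.0),
            input=dh.StationaryInput(kind="white", phi=0.0, sigma=1.0))
        s = dh.recurrent_moment_surface(unit)
        assert s.nu(0.0, 0.0) == pytest.approx(2.5)  # eta^2/2 at g=0
        assert s.mu(1.0, 0.5) == pytest.approx(2.0)
        assert s.nu(1.0, 0.5) == pytest.approx(5.25)

    def test_variance_monotone_and_divergent_toward_unity(self):
        unit = dh.SelfExcitatoryUnit(
            eta=1.0, input=dh.StationaryInput(kind="white", phi=0.0, sigma=1.0))
        s = dh.recurrent_moment_surface(unit)
        nus = [s.nu(0.0, g) for g in (0.0, 0.5, 0.9, 0.99, 0.999)]
        assert all(a < b for a, b in zip(nus, nus[1:]))
        assert nus[-1] > 500.0

    def test_runaway_gain_rejected(self):
        s = dh.recurrent_moment_surface(dh.SelfExcitatoryUnit())
        with pytest.raises(ValueError):
            s.nu(0.0, 1.0)

    def test_simulated_variance_grows_toward_integrator_point(self):
        unit = dh.SelfExcitatoryUnit(
            eta=1.0, input=dh.StationaryInput(kind="constant", phi=0.0))
        vs = []
        for g in (0.0, 0.5, 0.9, 0.99):
            _, r = dh.simulate_fast(unit, dh.ControlState(0.0, g),
                                    T=2000.0, dt=0.005, seed=9, r0=0.0)
            vs.append(np.var(r[len(r) // 4:]))
        assert all(a < b for a, b in zip(vs, vs[1:]))


@pytest.mark.parametrize("make_unit", [
    lambda: dh.OURateUnit(tau_r=0.4, eta=0.7, input=dh.StationaryInput(
        kind="white", phi=1.5, sigma=0.6)),
    lambda: dh.PoissonCalciumUnit(delta=0.8, tau_d=1.5, input=dh.StationaryInput(
        kind="ou_correlated", phi=1.0, sigma_I=0.4, tau_I=3.0)),
    lambda: dh.SelfExcitatoryUnit(eta=1.2, input=dh.StationaryInput(
        kind="white", phi=0.5, sigma=1.0)),
])
def test_surface_partials_match_finite_differences(make_unit):
    unit = make_unit()
    s = dh.moment_surface(unit)
    a, b = 1.3, 0.6
    h = 1e-6
    fd = {
        "dmu_da": (s.mu(a + h, b) - s.mu(a - h, b)) / (2 * h),
        "dmu_db": (s.mu(a, b + h) - s.mu(a, b - h)) / (2 * h),
        "dnu_da": (s.nu(a + h, b) - s.nu(a - h, b)) / (2 * h),
        "dnu_db": (s.nu(a, b + h) - s.nu(a, b - h)) / (2 * h),
    }
    p = s.at(a, b)
    for key, val in fd.items():
        assert getattr(p, key) == pytest.approx(val, rel=1e-5, abs=1e-9)


class TestSimulateFast:
    def test_deterministic_relaxation_to_asymptote(self):
        unit = dh.OURateUnit(tau_r=0.2,
                             input=dh.StationaryInput(kind="constant", phi=2.0))
        t, r = dh.simulate_fast(unit, dh.ControlState(1.0, 1.5), T=5.0,
                                dt=0.001, seed=0, r0=0.0)
        target = 1.5 * 2.0 + 1.0
        assert r[-1] == pytest.approx(target, rel=1e-3)
        # exponential approach with time constant tau_r
        k = np.searchsorted(t, 0.2)
        assert r[k] == pytest.approx(target * (1 - math.exp(-1)), rel=0.02)

    def test_zero_input_zero_noise_stays_zero(self):
        unit = dh.OURateUnit(tau_r=0.2,
                             input=dh.StationaryInput(kind="constant", phi=0.0))
        _, r = dh.simulate_fast(unit, dh.ControlState(0.0, 1.0), T=2.0,
                                dt=0.001, seed=0, r0=0.0)
        assert np.all(r == 0.0)

    def test_same_seed_same_trajectory(self):
        unit = dh.OURateUnit(tau_r=0.2, eta=0.3, input=dh.StationaryInput(
            kind="white", phi=1.0, sigma=0.5))
        _, r1 = dh.simulate_fast(unit, dh.ControlState(0.0, 1.0), 10.0, 0.001, seed=42)
        _, r2 = dh.simulate_fast(unit, dh.ControlState(0.0, 1.0), 10.0, 0.001, seed=42)
        _, r3 = dh.simulate_fast(unit, dh.ControlState(0.0, 1.0), 10.0, 0.001, seed=43)
        assert np.array_equal(r1, r2)
        assert not np.array_equal(r1, r3)

    def test_step_size_guard(self):
        unit = dh.OURateUnit(tau_r=0.1)
        with pytest.raises(StepSizeError):
            dh.simulate_fast(unit, dh.ControlState(0.0, 1.0), 1.0, 0.05)

    def test_sensor_mean_invariant_to_dt_refinement(self):
        unit = dh.PoissonCalciumUnit(delta=1.0, tau_d=2.0)
        means = []
        for dt in (0.02, 0.005):
            _, rho = dh.simulate_fast(unit, dh.ControlState(0.0, 1.0),
                                      T=4000.0, dt=dt, seed=5)
            means.append(np.mean(rho[len(rho) // 10:]))
        assert means[0] == pytest.approx(means[1], rel=0.05)
        assert means[1] == pytest.approx(2.0, rel=0.05)


class TestSampleInput:
    def test_ou_input_stationary_statistics(self):
        inp = dh.StationaryInput(kind="ou_correlated", phi=2.0,
                                 sigma_I=0.5, tau_I=1.0)
        rng = np.random.default_rng(3)
        I = sample_input(inp, 400_000, 0.01, rng)
        assert np.mean(I) == pytest.approx(2.0, abs=0.02)
        assert np.std(I) == pytest.approx(0.5, rel=0.05)
        # autocorrelation at lag tau_I is ~ 1/e
        dev = I - np.mean(I)
        lag = 100
        rho = np.mean(dev[:-lag] * dev[lag:]) / np.var(dev)
        assert rho == pytest.approx(math.exp(-1), abs=0.05)

    def test_pulse_train_shape(self):
        inp = dh.StationaryInput(kind="pulses", phi=1.0, pulse_amplitude=2.0,
                                 pulse_width=0.5, pulse_interval=2.0,
                                 n_pulses=2, pulse_start=1.0)
        I = sample_input(inp, 600, 0.01, np.random.default_rng(0))
        t = np.arange(600) * 0.01
        assert np.all(I[(t >= 1.0) & (t < 1.5)] == 3.0)
        assert np.all(I[t < 1.0] == 1.0)
        assert np.all(I[(t >= 1.5) & (t < 3.0)] == 1.0)
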