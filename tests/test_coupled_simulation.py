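"""Slow-fast coupled simulation, empirical moments, outcome classification."""

import math

import numpy as np
import pytest

import dualhomeo as dh
from dualhomeo.coupled_simulation import (InsufficientDataError,
                                          OutcomeThresholds, SimulationResult)


def make_result(times, a, b, rate=None, relax=0.1):
    return SimulationResult(
        times=np.asarray(times, float),
        rate=np.asarray(rate if rate is not None else np.zeros_like(times), float),
        a=np.asarray(a, float), b=np.asarray(b, float),
        dt=float(times[1] - times[0]), seed=0, burn_in=0.0, relax_time=relax)


class TestSimulateDual:
    def test_bit_identical_reproducibility(self, canonical_cfg):
        unit = dh.OURateUnit(tau_r=0.1, input=dh.StationaryInput(
            kind="white", phi=1.0, sigma=0.1))
        kw = dict(T=50.0, dt=0.002, seed=7)
        r1 = dh.simulate_dual(unit, canonical_cfg, dh.ControlState(0.0, 1.0), **kw)
        r2 = dh.simulate_dual(unit, canonical_cfg, dh.ControlState(0.0, 1.0), **kw)
        assert np.array_equal(r1.rate, r2.rate)
        assert np.array_equal(r1.a, r2.a)
        assert np.array_equal(r1.b, r2.b)

    def test_multiplicative_gain_stays_positive(self, canonical_cfg):
        unit = dh.OURateUnit(tau_r=0.1, input=dh.StationaryInput(
            kind="white", phi=1.0, sigma=0.03162277660168379))
        res = dh.simulate_dual(unit, canonical_cfg,
                               dh.ControlState(3.5, 0.5), T=500.0, dt=0.002,
                               seed=0)
        assert np.all(res.b > 0)

    def test_general_control_functions_rejected(self):
        cfg = dh.DualControlConfig(fa=dh.exponential(0.2), fb=dh.quadratic(c2=1.0),
                                   r_a=2.0, r_b=3.0)
        unit = dh.OURateUnit()
        with pytest.raises(TypeError):
            dh.simulate_dual(unit, cfg, dh.ControlState(0.0, 1.0), 10.0, 0.002)

    def test_poisson_sensor_homeostasis_converges(self):
        """Dual control of the calcium sensor reaches the characteristic
        sensor moments (OU-correlated drive keeps the intensity positive)."""
        inp = dh.StationaryInput(kind="ou_correlated", phi=1.0,
                                 sigma_I=0.5, tau_I=5.0)
        unit = dh.PoissonCalciumUnit(delta=1.0, tau_d=2.0, input=inp)
        # sensor-unit targets: mu* = 4, nu* = r_b^2 - r_a^2 = 4
        cfg = dh.DualControlConfig(fa=dh.linear(), fb=dh.quadratic(c2=1.0),
                                   r_a=4.0, r_b=math.sqrt(20.0),
                                   tau_a=200.0, tau_b=2000.0)
        res = dh.simulate_dual(unit, cfg, dh.ControlState(0.5, 1.0),
                               T=12000.0, dt=0.01, seed=3)
        assert res.outcome == "converged"
        eq = res.equilibrium
        assert abs(eq["mean_r"] - 4.0) < max(3 * eq["se_mean"], 0.15)
        assert abs(eq["var_r"] - 4.0) < max(3 * eq["se_var"], 0.6)


class TestSimulateAveraged:
    def test_fixed_point_is_stationary(self, canonical_cfg, white_unit):
        surf = dh.ou_moment_surface(white_unit)
        rep = dh.find_fixed_point(surf, canonical_cfg)
        a0, b0 = rep.location
        res = dh.simulate_averaged(surf, canonical_cfg,
                                   dh.ControlState(a0, b0), T=5000.0)
        assert res.outcome == "converged"
        assert res.a[-1] == pytest.approx(a0, abs=1e-6)
        assert res.b[-1] == pytest.approx(b0, abs=1e-6)

    def test_converges_to_closed_form_fixed_point(self, canonical_cfg):
        """The varying-input averaged flow lands on the closed-form
        (x*, g*) = (r_x - phi sqrt(2 tau_r (r_g^2-r_x^2))/sigma, ...)."""
        sigma, tau_r, phi = 0.2, 0.1, 1.0
        unit = dh.OURateUnit(tau_r=tau_r, input=dh.StationaryInput(
            kind="white", phi=phi, sigma=sigma))
        surf = dh.ou_moment_surface(unit)
        g_star = math.sqrt(2 * tau_r * 6.0) / sigma
        x_star = 2.5 - phi * g_star
        res = dh.simulate_averaged(surf, canonical_cfg,
                                   dh.ControlState(0.0, 1.0), T=60000.0)
        assert res.outcome == "converged"
        assert res.a[-1] == pytest.approx(x_star, rel=1e-4)
        assert res.b[-1] == pytest.approx(g_star, rel=1e-4)

    def test_constant_input_nullclines_and_degenerate_line(self):
        """With constant input and equal targets the averaged flow stops on
        the line g phi + x = target, from several initial conditions."""
        unit = dh.OURateUnit(tau_r=0.1,
                             input=dh.StationaryInput(kind="constant", phi=1.0))
        surf = dh.ou_moment_surface(unit)
        cfg = dh.DualControlConfig(fa=dh.linear(), fb=dh.quadratic(c2=1.0),
                                   r_a=3.0, r_b=3.0, tau_a=100.0, tau_b=1000.0)
        endpoints = []
        for (a0, b0) in [(0.0, 0.5), (4.0, 2.0), (-1.0, 1.0)]:
            res = dh.simulate_averaged(surf, cfg, dh.ControlState(a0, b0),
                                       T=30000.0)
            assert res.outcome == "converged"
            endpoints.append((res.a[-1], res.b[-1]))
            assert res.b[-1] * 1.0 + res.a[-1] == pytest.approx(3.0, abs=1e-6)
        # distinct endpoints: a line of fixed points, not a single point
        assert np.std([e[1] for e in endpoints]) > 0.1

    def test_domain_exit_reported_not_raised(self):
        # negative sensor targets drive the Poisson intensity to its
        # positivity boundary: the averaged flow leaves the surface domain
        unit = dh.PoissonCalciumUnit(delta=1.0, tau_d=2.0)
        surf = dh.poisson_calcium_moment_surface(unit)
        cfg = dh.DualControlConfig(fa=dh.linear(),
                                   fb=dh.quadratic(c1=1.0, c2=0.05),
                                   r_a=-2.0, r_b=-2.0, tau_a=10.0, tau_b=10.0)
        res = dh.simulate_averaged(surf, cfg, dh.ControlState(1.0, 1.0),
                                   T=5000.0)
        assert res.outcome == "domain_exit"


class TestEmpiricalMoments:
    def test_constant_trace(self):
        t = np.arange(0, 100.0, 0.1)
        res = make_result(t, np.zeros_like(t), np.ones_like(t),
                          rate=np.full_like(t, 3.3), relax=0.1)
        m = dh.empirical_moments(res, burn_in=0.0)
        assert m.mean == pytest.approx(3.3, rel=1e-14)
        assert m.variance == pytest.approx(0.0, abs=1e-24)

    def test_ou_trace_matches_surface_within_3se(self, white_unit):
        s = dh.ou_moment_surface(white_unit)
        x, g = 0.5, 1.5
        t, r = dh.simulate_fast(white_unit, dh.ControlState(x, g),
                                T=4000.0, dt=0.002, seed=13)
        res = make_result(t, np.zeros_like(t), np.ones_like(t), rate=r,
                          relax=white_unit.tau_r)
        m = dh.empirical_moments(res, burn_in=100.0)
        assert abs(m.mean - s.mu(x, g)) < 3 * m.se_mean
        assert abs(m.variance - s.nu(x, g)) < 3 * m.se_variance

    def test_se_shrinks_with_window(self, white_unit):
        t, r = dh.simulate_fast(white_unit, dh.ControlState(0.0, 1.0),
                                T=8000.0, dt=0.002, seed=14)
        res = make_result(t, np.zeros_like(t), np.ones_like(t), rate=r,
                          relax=white_unit.tau_r)
        m_short = dh.empirical_moments(res, burn_in=t[-1] - 500.0)
        m_long = dh.empirical_moments(res, burn_in=0.0)
        # 16x window: batch-means SE should shrink roughly 4x
        assert m_long.se_mean < 0.6 * m_short.se_mean
        assert m_long.se_variance < 0.6 * m_short.se_variance

    def test_window_too_short(self):
        t = np.arange(0, 1.0, 0.01)
        res = make_result(t, np.zeros_like(t), np.ones_like(t),
                          rate=np.sin(t), relax=0.5)
        with pytest.raises(InsufficientDataError):
            dh.empirical_moments(res, burn_in=0.0)


class TestClassifyOutcome:
    def test_windup_signature(self):
        t = np.linspace(0, 100, 500)
        res = make_result(t, a=1.0 - 0.5 * t, b=np.exp(0.05 * t))
        assert dh.classify_outcome(res) == "windup"

    def test_elimination_signature(self):
        t = np.linspace(0, 100, 500)
        res = make_result(t, a=3.0 + 0.01 * np.sin(t), b=np.exp(-0.2 * t))
        assert dh.classify_outcome(res) == "synapse_elimination"

    def test_converged_signature(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 100, 2000)
        res = make_result(t, a=2.0 + 0.05 * rng.standard_normal(len(t)),
                          b=1.0 + 0.05 * rng.standard_normal(len(t)))
        assert dh.classify_outcome(res) == "converged"

    def test_steady_drift_is_not_convergence(self):
        t = np.linspace(0, 100, 2000)
        res = make_result(t, a=2.0 + 0.02 * t, b=np.full_like(t, 1.0))
        assert dh.classify_outcome(res) == "undetermined"


class TestSmallEpsilonContract:
    def test_slow_variable_spread_shrinks_with_epsilon(self, canonical_cfg):
        """Halving the homeostatic speed (epsilon) tightens the trapped
        ball around the averaged fixed point, monotonically over a 10x
        range."""
        unit = dh.OURateUnit(tau_r=0.1, input=dh.StationaryInput(
            kind="white", phi=1.0, sigma=0.5))
        g_star = math.sqrt(2 * 0.1 * 6.0) / 0.5
        x_star = 2.5 - g_star
        spreads = []
        for eps in (1.0, 0.32, 0.1):
            cfg = dh.DualControlConfig(
                fa=canonical_cfg.fa, fb=canonical_cfg.fb, r_a=2.5, r_b=3.5,
                tau_a=20.0, tau_b=200.0, epsilon=eps)
            res = dh.simulate_dual(unit, cfg, dh.ControlState(x_star, g_star),
                                   T=4000.0 / eps, dt=0.002, seed=21)
            w = res.times >= 0.5 * res.times[-1]
            spreads.append(float(np.std(res.a[w]) + np.std(res.b[w])))
        assert spreads[0] > spreads[1] > spreads[2]

    def test_full_endpoint_near_averaged_endpoint(self, canonical_cfg):
        unit = dh.OURateUnit(tau_r=0.1, input=dh.StationaryInput(
            kind="white", phi=1.0, sigma=0.5))
        surf = dh.ou_moment_surface(unit)
        init = dh.ControlState(0.0, 1.0)
        avg = dh.simulate_averaged(surf, canonical_cfg, init, T=8000.0)
        full = dh.simulate_dual(unit, canonical_cfg, init, T=8000.0,
                                dt=0.002, seed=2)
        d = math.hypot(full.a[-1] - avg.a[-1], full.b[-1] - avg.b[-1])
        scale = max(abs(avg.a[-1]), abs(avg.b[-1]), 1.0)
        assert d < 0.25 * scale
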