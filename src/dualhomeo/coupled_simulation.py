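"""Slow-fast coupled simulation of dual homeostatic control.

Integrates the full stochastic system (fast rate/sensor dynamics coupled to
two slow feedback variables) and its deterministic averaged counterpart (the
two-dimensional slow ODE obtained by replacing fast-rate functionals with
their stationary expectations), estimates empirical stationary moments with
autocorrelation-aware standard errors, and classifies trajectory outcomes
into converged / wind-up / synapse-elimination.

The time-scale separation is realized by choosing the slow time constants
``tau_a/epsilon`` and ``tau_b/epsilon`` large against the fast relaxation
time; a single seed controls all randomness per run, with input noise and
intrinsic noise drawn from independent substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernels
from .control_laws import DualControlConfig, averaged_drift
from .neuron_models import (ControlState, MomentSurface,
                            PoissonCalciumUnit, SelfExcitatoryUnit,
                            StepSizeError, Unit, sample_input)

__all__ = [
    "OutcomeThresholds",
    "SimulationResult",
    "Moments",
    "InsufficientDataError",
    "simulate_dual",
    "simulate_averaged",
    "empirical_moments",
    "classify_outcome",
]


class InsufficientDataError(ValueError):
    """Post-burn-in window too short for moment estimation."""


@dataclass(frozen=True)
class OutcomeThresholds:
    """Operational criteria for trajectory outcome labels.

    ``windup_factor``: |a| exceeding this multiple of its initial scale,
    with drift of consistent sign over the final half of the run, counts as
    controller wind-up.  ``elimination_fraction``: b falling below this
    fraction of its initial value counts as synapse elimination.
    ``ball_radius``: relative radius of the trapped ball (fraction of the
    center's scale) within which the (a, b) trajectory must dwell for the
    final ``dwell_fraction`` of the run to count as converged; dwelling
    additionally requires no net drift (the centers of the two halves of
    the dwell window must agree to within half the observed deviation).
    """

    windup_factor: float = 10.0
    elimination_fraction: float = 1e-3
    ball_radius: float = 0.5
    dwell_fraction: float = 0.25


@dataclass
class SimulationResult:
    """Trajectory of (rate, a, b) on one time grid plus outcome metadata.

    For averaged runs the ``rate`` column carries the deterministic
    stationary mean ``mu(a(t), b(t))`` along the trajectory (there is no
    fluctuating rate trace to record).  ``equilibrium`` holds post-burn-in
    window statistics and is populated only when ``outcome == 'converged'``.
    """

    times: np.ndarray
    rate: np.ndarray
    a: np.ndarray
    b: np.ndarray
    dt: float
    seed: int | None
    burn_in: float
    outcome: str = "undetermined"
    equilibrium: dict = field(default_factory=dict)
    relax_time: float = 0.0
    kind: str = "stochastic"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "r": self.rate,
                             "x": self.a, "g": self.b})

    def window(self, start: float) -> np.ndarray:
        return self.times >= start


def _require_quadratic(cfg: DualControlConfig) -> None:
    if not (cfg.fa.is_quadratic and cfg.fb.is_quadratic):
        raise TypeError(
            "the stochastic kernels support the canonical quadratic "
            "control-function family only; use simulate_averaged for "
            "general smooth control functions")


def _slow_rates(cfg: DualControlConfig) -> tuple[float, float]:
    return cfg.epsilon / cfg.tau_a, cfg.epsilon / cfg.tau_b


def simulate_dual(unit: Unit, cfg: DualControlConfig, init: ControlState,
                  T: float, dt: float, seed: int = 0,
                  record_stride: int | None = None,
                  thresholds: OutcomeThresholds | None = None,
                  r0: float | None = None) -> SimulationResult:
    """Integrate the full stochastic slow-fast system.

    The fast variable advances by Euler-Maruyama (rate units) or exact
    decay with per-bin Poisson jumps (calcium sensor); both slow variables
    advance with the same step, a multiplicative mechanism in log
    coordinates (so it stays positive).  ``record_stride`` thins the stored
    trace (default: about 20 000 recorded samples); the integration itself
    always runs at ``dt``.  Bit-identical traces for identical
    (config, seed, dt).
    """
    _require_quadratic(cfg)
    thresholds = thresholds or OutcomeThresholds()
    n = int(round(T / dt))
    if record_stride is None:
        record_stride = max(1, n // 20000)

    ss = np.random.SeedSequence(seed)
    s_input, s_intr = ss.spawn(2)
    rng_in = np.random.default_rng(s_input)
    a0c, a1c, a2c = cfg.fa.coeffs
    b0c, b1c, b2c = cfg.fb.coeffs
    fa_t = float(cfg.fa.f(cfg.r_a))
    fb_t = float(cfg.fb.f(cfg.r_b))
    rate_a, rate_b = _slow_rates(cfg)

    if isinstance(unit, PoissonCalciumUnit):
        if dt >= 0.5 * unit.tau_d:
            raise StepSizeError(f"dt={dt} too large for tau_d={unit.tau_d}")
        I = sample_input(unit.input, n, dt, rng_in)
        rho0 = r0 if r0 is not None else \
            unit.delta * unit.tau_d * max(init.b * unit.input.phi + init.a, 0.0)
        kernel_seed = int(np.random.default_rng(s_intr).integers(2 ** 31 - 1))
        r_tr, a_tr, b_tr = _kernels.dual_poisson_kernel(
            I, dt, unit.tau_d, unit.delta, kernel_seed,
            a0c, a1c, a2c, fa_t, b0c, b1c, b2c, fb_t,
            rate_a, rate_b, cfg.multiplicative_a, cfg.multiplicative_b,
            rho0, init.a, init.b, record_stride)
        relax = unit.tau_d
    else:
        recurrent = isinstance(unit, SelfExcitatoryUnit)
        tau_r = 1.0 if recurrent else unit.tau_r
        if dt >= 0.5 * tau_r:
            raise StepSizeError(f"dt={dt} too large for tau_r={tau_r}")
        I = sample_input(unit.input, n, dt, rng_in)
        xi = np.random.default_rng(s_intr).standard_normal(n) \
            if unit.eta > 0 else np.zeros(n)
        if r0 is None:
            base = init.b * unit.input.phi + init.a
            r0 = base / max(1.0 - init.b, 1e-6) if recurrent else base
        r_tr, a_tr, b_tr = _kernels.dual_rate_kernel(
            I, xi, dt, tau_r, recurrent, unit.eta,
            a0c, a1c, a2c, fa_t, b0c, b1c, b2c, fb_t,
            rate_a, rate_b, cfg.multiplicative_a, cfg.multiplicative_b,
            r0, init.a, init.b, record_stride)
        relax = tau_r

    times = np.arange(len(r_tr)) * (dt * record_stride)
    times[-1] = T  # final state is appended exactly at the horizon
    burn_in = 0.5 * T
    result = SimulationResult(
        times=times, rate=r_tr, a=a_tr, b=b_tr, dt=dt, seed=seed,
        burn_in=burn_in, relax_time=relax, kind="stochastic")
    result.outcome = classify_outcome(result, thresholds)
    if result.outcome == "converged":
        try:
            mom = empirical_moments(
                result, burn_in=T * (1 - thresholds.dwell_fraction))
            w = result.window(result.times[-1] - thresholds.dwell_fraction * T)
            result.equilibrium = {
                "mean_r": mom.mean, "var_r": mom.variance,
                "se_mean": mom.se_mean, "se_var": mom.se_variance,
                "mean_a": float(np.mean(result.a[w])),
                "mean_b": float(np.mean(result.b[w])),
            }
        except InsufficientDataError:
            pass
    return result


def simulate_averaged(surface: MomentSurface, cfg: DualControlConfig,
                      init: ControlState, T: float,
                      n_points: int = 2000,
                      thresholds: OutcomeThresholds | None = None,
                      rtol: float = 1e-9, atol: float = 1e-11) -> SimulationResult:
    """Integrate the deterministic averaged slow ODE on a moment surface.

    The state is (a, b) — or (a, log b) for a multiplicative mechanism —
    and the drift is the averaged feedback evaluated at the surface's
    stationary moments.  If the trajectory exits the surface domain (e.g.
    the recurrent gain reaching 1) integration stops and the outcome is
    ``domain_exit`` rather than an exception.
    """
    thresholds = thresholds or OutcomeThresholds()
    rate_a, rate_b = _slow_rates(cfg)
    la = cfg.multiplicative_a
    lb = cfg.multiplicative_b

    def unpack(y):
        a = math.exp(y[0]) if la else y[0]
        b = math.exp(y[1]) if lb else y[1]
        return a, b

    def rhs(t, y):
        a, b = unpack(y)
        if not surface.in_domain(a, b):
            return [0.0, 0.0]
        mu = float(surface.mu(a, b))
        nu = float(surface.nu(a, b))
        Fa, Fb = averaged_drift(cfg, mu, max(nu, 0.0))
        return [rate_a * Fa, rate_b * Fb]

    def exit_event(t, y):
        a, b = unpack(y)
        return 1.0 if surface.in_domain(a, b) else -1.0
    exit_event.terminal = True

    y0 = [math.log(init.a) if la else init.a,
          math.log(init.b) if lb else init.b]
    if (la and init.a <= 0) or (lb and init.b <= 0):
        raise ValueError("multiplicative state must start positive")

    sol = solve_ivp(rhs, (0.0, T), y0, method="LSODA", rtol=rtol, atol=atol,
                    dense_output=True, events=exit_event)
    t_end = sol.t[-1]
    times = np.linspace(0.0, t_end, n_points)
    Y = sol.sol(times)
    a_tr = np.exp(Y[0]) if la else Y[0]
    b_tr = np.exp(Y[1]) if lb else Y[1]
    mu_tr = np.array([surface.mu(ai, bi) if surface.in_domain(ai, bi) else np.nan
                      for ai, bi in zip(a_tr, b_tr)])

    result = SimulationResult(
        times=times, rate=mu_tr, a=a_tr, b=b_tr,
        dt=times[1] - times[0] if len(times) > 1 else T, seed=None,
        burn_in=0.5 * t_end, kind="averaged")
    if sol.status == 1 and t_end < T:  # stopped by the domain-exit event
        result.outcome = "domain_exit"
        return result
    result.outcome = classify_outcome(result, thresholds)
    if result.outcome == "converged":
        a_end, b_end = float(a_tr[-1]), float(b_tr[-1])
        result.equilibrium = {
            "mean_r": float(surface.mu(a_end, b_end)),
            "var_r": float(surface.nu(a_end, b_end)),
            "se_mean": 0.0, "se_var": 0.0,
            "mean_a": a_end, "mean_b": b_end,
        }
    return result


@dataclass(frozen=True)
class Moments:
    """Stationary moment estimates with batch-means standard errors."""

    mean: float
    variance: float
    se_mean: float
    se_variance: float
    n_batches: int


def empirical_moments(result: SimulationResult, burn_in: float | None = None,
                      n_batches: int = 20,
                      min_relax_times: float = 100.0) -> Moments:
    """Post-burn-in mean and variance of the fast trace with batch-means SEs.

    The window is split into ``n_batches`` contiguous batches; the standard
    error of each moment is the spread of the per-batch estimates divided by
    ``sqrt(n_batches)``, which absorbs the trace autocorrelation as long as
    batches are long against the relaxation time.  Requires the window to
    cover at least ``min_relax_times`` fast relaxation times.
    """
    burn_in = result.burn_in if burn_in is None else burn_in
    w = result.window(burn_in)
    trace = np.asarray(result.rate)[w]
    if trace.size < 2 * n_batches:
        raise InsufficientDataError(
            f"window has {trace.size} samples; need at least {2 * n_batches}")
    window_T = float(result.times[-1] - burn_in)
    if result.relax_time > 0 and window_T < min_relax_times * result.relax_time:
        raise InsufficientDataError(
            f"window {window_T:g} shorter than {min_relax_times:g} "
            f"relaxation times ({result.relax_time:g} each)")
    batches = np.array_split(trace, n_batches)
    bm = np.array([np.mean(b) for b in batches])
    bv = np.array([np.var(b) for b in batches])
    return Moments(
        mean=float(np.mean(trace)),
        variance=float(np.var(trace)),
        se_mean=float(np.std(bm, ddof=1) / math.sqrt(n_batches)),
        se_variance=float(np.std(bv, ddof=1) / math.sqrt(n_batches)),
        n_batches=n_batches,
    )


def classify_outcome(result: SimulationResult,
                     thresholds: OutcomeThresholds | None = None) -> str:
    """Deterministic outcome label for a slow-variable trajectory.

    Checked in order: synapse elimination (b below a small fraction of its
    initial value), wind-up (|a| far beyond its initial scale and still
    drifting in a consistent direction over the final half), convergence
    (the (a, b) trajectory dwells inside a trapped ball for the final
    fraction of the run).  Anything else is ``undetermined``.
    """
    th = thresholds or OutcomeThresholds()
    a, b, t = np.asarray(result.a), np.asarray(result.b), np.asarray(result.times)
    if len(a) < 8:
        return "undetermined"

    # wind-up first: unbounded monotone a-drift is the defining signature,
    # and g may simultaneously collapse (strong intrinsic noise) or grow
    a_scale = max(abs(a[0]), 1.0)
    half = t >= 0.5 * t[-1]
    if abs(a[-1]) > th.windup_factor * a_scale:
        # coarse-grain before testing drift direction: per-step increments
        # are noise-dominated, segment means expose the ramp
        segs = [np.mean(s) for s in np.array_split(a[half], 16) if len(s)]
        da = np.diff(segs)
        sgn = np.mean(np.sign(da[da != 0])) if np.any(da != 0) else 0.0
        if abs(sgn) > 0.8:
            return "windup"
    # b exploding upward with a ramping away is the same tug-of-war
    if abs(b[-1]) > th.windup_factor * max(abs(b[0]), 1.0) \
            and abs(a[-1] - a[0]) > a_scale:
        return "windup"

    if abs(b[-1]) < th.elimination_fraction * max(abs(b[0]), 1e-300):
        return "synapse_elimination"

    dwell = t >= (1.0 - th.dwell_fraction) * t[-1]
    ad, bd = a[dwell], b[dwell]
    ca, cb = np.mean(ad), np.mean(bd)
    scale = max(abs(ca), abs(cb), 1.0)
    dev = np.sqrt((ad - ca) ** 2 + (bd - cb) ** 2)
    maxdev = float(np.max(dev))
    half_n = len(ad) // 2
    shift = math.hypot(np.mean(ad[half_n:]) - np.mean(ad[:half_n]),
                       np.mean(bd[half_n:]) - np.mean(bd[:half_n]))
    trapped = maxdev <= th.ball_radius * scale
    stationary = shift <= max(0.5 * maxdev, 1e-9 * scale)
    if trapped and stationary:
        return "converged"
    return "undetermined"
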