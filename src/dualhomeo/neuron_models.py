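"""Neuron and rate-sensor models with analytic moment surfaces.

Each model exposes two things:

* a :class:`MomentSurface` — the maps ``mu(a, b)`` and ``nu(a, b)`` giving
  the stationary firing-rate (or sensor) mean and variance as functions of
  the two homeostatic control variables, together with their partial
  derivatives.  The surface is everything the fixed-point and stability
  layers need to know about the neuron.
* a fast stochastic simulator (:func:`simulate_fast`) of the rate dynamics
  at frozen control state, used to validate the analytic surface and to
  drive the coupled slow-fast simulation.

Models
------
``OURateUnit``
    Linear rate unit ``tau_r dr/dt = -r + g I(t) + x + eta xi(t)``.  With
    second-order stationary input the rate is a filtered stationary process
    with ``mu = g phi + x`` and ``nu = (g^2 C + eta^2) / (2 tau_r)`` where
    the constant ``C`` summarizes the input autocovariance seen through the
    rate filter.
``PoissonCalciumUnit``
    Poisson spiking with intensity ``lambda(t) = g I(t) + x`` (clamped at
    zero) driving a calcium-like sensor that jumps by ``delta`` per spike
    and decays with time constant ``tau_d``.  Stationary sensor moments:
    ``mu = delta tau_d (g phi + x)`` and
    ``nu = delta^2 tau_d (C g^2 + (g phi + x)/2)``.
``SelfExcitatoryUnit``
    Recurrent excitatory unit ``dr/dt = -r + g (r + I(t)) + x + eta xi(t)``
    (time rescaled so ``tau_r = 1``), valid for ``g < 1``:
    ``mu = (g phi + x)/(1 - g)`` and
    ``nu = (g^2 C + eta^2) / (2 (1 - g))``.  As ``g -> 1`` the variance
    diverges and the unit becomes an integrator.

Rate variables are deliberately allowed to go negative in the linear rate
models (they are analyzed without rectification); only the Poisson
intensity is clamped at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import dblquad
from scipy.signal import lfilter

__all__ = [
    "StationaryInput",
    "ControlState",
    "OURateUnit",
    "PoissonCalciumUnit",
    "SelfExcitatoryUnit",
    "MomentSurface",
    "SurfacePoint",
    "NonStationaryInputError",
    "StepSizeError",
    "filtered_input_constant",
    "filtered_input_constant_quadrature",
    "ou_moment_surface",
    "poisson_calcium_moment_surface",
    "recurrent_moment_surface",
    "moment_surface",
    "sample_input",
    "simulate_fast",
]


class NonStationaryInputError(ValueError):
    """Input process is not second-order stationary (e.g. pulse trains)."""


class StepSizeError(ValueError):
    """Integration step too coarse for the fastest time constant."""


# ---------------------------------------------------------------------------
# Inputs


@dataclass(frozen=True)
class StationaryInput:
    """Synaptic input process ``I(t)`` with stationary mean ``phi``.

    kind
        ``constant`` — ``I(t) = phi``, autocovariance identically zero.
        ``white`` — ``I(t) = phi + sigma xi(t)`` with unit-variance white
        noise ``xi``; delta autocovariance ``sigma^2 delta(w)``.
        ``ou_correlated`` — Ornstein-Uhlenbeck input with stationary
        standard deviation ``sigma_I`` and correlation time ``tau_I``;
        autocovariance ``sigma_I^2 exp(-|w|/tau_I)``.
        ``pulses`` — deterministic rectangular pulse train on top of a
        baseline; *not* second-order stationary, used only by the
        integrator pulse tests.
    """

    kind: str = "constant"
    phi: float = 1.0
    sigma: float = 0.0
    tau_I: float = 10.0
    sigma_I: float = 0.0
    pulse_amplitude: float = 0.0
    pulse_width: float = 0.0
    pulse_interval: float = 0.0
    n_pulses: int = 0
    pulse_start: float = 0.0

    _KINDS = ("constant", "white", "ou_correlated", "pulses")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown input kind {self.kind!r}; "
                             f"expected one of {self._KINDS}")
        if self.kind == "ou_correlated" and not self.tau_I > 0:
            raise ValueError("ou_correlated input requires tau_I > 0")

    @property
    def is_stationary(self) -> bool:
        return self.kind != "pulses"

    def to_config(self) -> dict:
        d = {"kind": self.kind, "phi": self.phi}
        if self.kind == "white":
            d["sigma"] = self.sigma
        elif self.kind == "ou_correlated":
            d.update(tau_I=self.tau_I, sigma_I=self.sigma_I)
        elif self.kind == "pulses":
            d.update(pulse_amplitude=self.pulse_amplitude,
                     pulse_width=self.pulse_width,
                     pulse_interval=self.pulse_interval,
                     n_pulses=self.n_pulses, pulse_start=self.pulse_start)
        return d


@dataclass
class ControlState:
    """Homeostatic control state: excitability-like ``a``, gain-like ``b``."""

    a: float
    b: float

    # aliases matching the synaptic/intrinsic interpretation
    @property
    def x(self) -> float:
        return self.a

    @property
    def g(self) -> float:
        return self.b


# ---------------------------------------------------------------------------
# Units


@dataclass(frozen=True)
class OURateUnit:
    """Linear rate unit: ``tau_r dr/dt = -r + g I(t) + x + eta xi(t)``."""

    tau_r: float = 0.1
    input: StationaryInput = field(default_factory=StationaryInput)
    eta: float = 0.0

    def __post_init__(self):
        if not self.tau_r > 0:
            raise ValueError("tau_r must be positive")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")


@dataclass(frozen=True)
class PoissonCalciumUnit:
    """Poisson spiker with jump-decay calcium sensor ``rho``."""

    delta: float = 1.0
    tau_d: float = 1.0
    input: StationaryInput = field(default_factory=StationaryInput)

    def __post_init__(self):
        if not (self.delta > 0 and self.tau_d > 0):
            raise ValueError("delta and tau_d must be positive")


@dataclass(frozen=True)
class SelfExcitatoryUnit:
    """Recurrent excitatory unit (time rescaled so tau_r = 1).

    Analytic moments are valid only for ``g < 1``; at ``g = 1`` the unit is
    a perfect (noisy) integrator and the stationary variance diverges.
    """

    eta: float = 0.0
    input: StationaryInput = field(default_factory=StationaryInput)

    tau_r: float = 1.0  # fixed by the time rescaling; kept for uniform code paths

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")


Unit = OURateUnit | PoissonCalciumUnit | SelfExcitatoryUnit


# ---------------------------------------------------------------------------
# Moment surfaces


@dataclass(frozen=True)
class SurfacePoint:
    """Moment surface evaluated at one control state."""

    mu: float
    nu: float
    dmu_da: float
    dmu_db: float
    dnu_da: float
    dnu_db: float

    def moment_jacobian_det(self) -> float:
        """``dmu/da dnu/db - dmu/db dnu/da`` — the surface factor of the
        stability criterion."""
        return self.dmu_da * self.dnu_db - self.dmu_db * self.dnu_da


@dataclass(frozen=True)
class MomentSurface:
    """Stationary mean/variance of the fast variable as functions of (a, b).

    ``nu_floor(mu)`` gives the model's variance floor — the smallest
    stationary variance achievable at a given mean (e.g. ``eta^2/(2 tau_r)``
    for the intrinsically noisy rate unit, ``delta mu / 2`` for the Poisson
    sensor).  Characteristic variances below the floor admit no fixed point.
    """

    mu: Callable[[float, float], float]
    nu: Callable[[float, float], float]
    dmu_da: Callable[[float, float], float]
    dmu_db: Callable[[float, float], float]
    dnu_da: Callable[[float, float], float]
    dnu_db: Callable[[float, float], float]
    nu_floor: Callable[[float], float] = lambda mu: 0.0
    in_domain: Callable[[float, float], bool] = lambda a, b: True
    label: str = "surface"

    def at(self, a: float, b: float) -> SurfacePoint:
        if not self.in_domain(a, b):
            raise ValueError(f"control state ({a}, {b}) outside {self.label} domain")
        return SurfacePoint(
            mu=float(self.mu(a, b)), nu=float(self.nu(a, b)),
            dmu_da=float(self.dmu_da(a, b)), dmu_db=float(self.dmu_db(a, b)),
            dnu_da=float(self.dnu_da(a, b)), dnu_db=float(self.dnu_db(a, b)))


def filtered_input_constant(input: StationaryInput, tau_r: float) -> float:
    """The filtered-autocovariance constant ``C`` of a stationary input.

    Defined operationally as the constant for which the linear rate unit's
    input-driven stationary variance is ``g^2 C / (2 tau_r)``:

    * constant input: ``C = 0``;
    * white input of amplitude sigma: ``C = sigma^2``;
    * OU-correlated input: ``C = 2 tau_r sigma_I^2 tau_I / (tau_I + tau_r)``
      (the classic filtered-OU variance ``sigma_I^2 tau_I/(tau_I + tau_r)``
      rescaled).

    Pulse trains are not stationary and have no ``C``.
    """
    if not input.is_stationary:
        raise NonStationaryInputError(
            "pulse-train input is not second-order stationary; C undefined")
    if input.kind == "constant":
        return 0.0
    if input.kind == "white":
        return float(input.sigma) ** 2
    # ou_correlated
    return 2.0 * tau_r * input.sigma_I ** 2 * input.tau_I / (input.tau_I + tau_r)


def filtered_input_constant_quadrature(input: StationaryInput, tau_r: float,
                                       window: float | None = None) -> float:
    """Slow numerical cross-check of ``C`` by direct double integration.

    Integrates the input autocovariance through the squared exponential rate
    filter,

        var = (1/tau_r^2) int_0^W int_0^W e^{-(u+v)/tau_r} R(u - v) du dv,

    and returns ``C = 2 tau_r var``.  Only meaningful for the
    ``ou_correlated`` kind (the white-noise delta autocovariance cannot be
    integrated numerically); kept as an independent check on the closed
    form.
    """
    if input.kind != "ou_correlated":
        raise ValueError("quadrature cross-check applies to ou_correlated input")
    s2, tI = input.sigma_I ** 2, input.tau_I
    # the filter kernel e^{-(u+v)/tau_r} bounds the support; a window much
    # wider than that only adds underflow-dominated roundoff
    W = window if window is not None else 30.0 * tau_r
    var, _ = dblquad(
        lambda u, v: math.exp(-(u + v) / tau_r) * s2 * math.exp(-abs(u - v) / tI),
        0.0, W, 0.0, W, epsabs=1e-10, epsrel=1e-8)
    return 2.0 * tau_r * var / tau_r ** 2


def ou_moment_surface(unit: OURateUnit) -> MomentSurface:
    """``mu = g phi + x``; ``nu = (g^2 C + eta^2) / (2 tau_r)``."""
    phi = unit.input.phi
    C = filtered_input_constant(unit.input, unit.tau_r)
    tr, eta2 = unit.tau_r, unit.eta ** 2
    return MomentSurface(
        mu=lambda x, g: g * phi + x,
        nu=lambda x, g: (g * g * C + eta2) / (2.0 * tr),
        dmu_da=lambda x, g: 1.0,
        dmu_db=lambda x, g: phi,
        dnu_da=lambda x, g: 0.0,
        dnu_db=lambda x, g: g * C / tr,
        nu_floor=lambda mu: eta2 / (2.0 * tr),
        label="OU rate unit",
    )


def poisson_calcium_moment_surface(unit: PoissonCalciumUnit) -> MomentSurface:
    """Sensor moments ``mu = delta tau_d (g phi + x)``,
    ``nu = delta^2 tau_d (C g^2 + (g phi + x)/2)``.

    The shot-noise term gives the reachability floor ``nu >= delta mu / 2``:
    Poisson spiking is inherently noisy, so arbitrarily small sensor
    variance at a given mean is unreachable.  Valid only where the mean
    intensity ``g phi + x`` is positive.
    """
    phi = unit.input.phi
    # C for the sensor filter (time constant tau_d): same operational
    # definition as for the rate unit, with the sensor as the filter
    C = filtered_input_constant(unit.input, unit.tau_d)
    d, td = unit.delta, unit.tau_d
    return MomentSurface(
        mu=lambda x, g: d * td * (g * phi + x),
        nu=lambda x, g: d * d * td * (C * g * g + 0.5 * (g * phi + x)),
        dmu_da=lambda x, g: d * td,
        dmu_db=lambda x, g: d * td * phi,
        dnu_da=lambda x, g: 0.5 * d * d * td,
        dnu_db=lambda x, g: d * d * td * (2.0 * C * g + 0.5 * phi),
        nu_floor=lambda mu: 0.5 * d * mu,
        in_domain=lambda x, g: (g * phi + x) > 0,
        label="Poisson/calcium unit",
    )


def recurrent_moment_surface(unit: SelfExcitatoryUnit) -> MomentSurface:
    """``mu = (g phi + x)/(1-g)``; ``nu = (g^2 C + eta^2)/(2 (1-g))``.

    ``nu`` is strictly increasing in ``g`` on [0, 1) and diverges as
    ``g -> 1``: tuning the characteristic variance high forces the gain
    toward the integrator point.
    """
    phi = unit.input.phi
    C = filtered_input_constant(unit.input, 1.0)
    eta2 = unit.eta ** 2

    def _check(g):
        if g >= 1.0:
            raise ValueError("runaway feedback: recurrent gain g must be < 1")

    def mu(x, g):
        _check(g)
        return (g * phi + x) / (1.0 - g)

    def nu(x, g):
        _check(g)
        return 0.5 * (g * g * C + eta2) / (1.0 - g)

    return MomentSurface(
        mu=mu,
        nu=nu,
        dmu_da=lambda x, g: 1.0 / (1.0 - g),
        dmu_db=lambda x, g: (phi + x) / (1.0 - g) ** 2,
        dnu_da=lambda x, g: 0.0,
        dnu_db=lambda x, g: (g * C * (1.0 - g) + 0.5 * (g * g * C + eta2))
        / (1.0 - g) ** 2,
        nu_floor=lambda mu: 0.5 * eta2,
        in_domain=lambda x, g: g < 1.0,
        label="self-excitatory unit",
    )


def moment_surface(unit: Unit) -> MomentSurface:
    """Dispatch to the analytic moment surface for a unit."""
    if isinstance(unit, OURateUnit):
        return ou_moment_surface(unit)
    if isinstance(unit, PoissonCalciumUnit):
        return poisson_calcium_moment_surface(unit)
    if isinstance(unit, SelfExcitatoryUnit):
        return recurrent_moment_surface(unit)
    raise TypeError(f"no analytic moment surface for {type(unit).__name__}")


# ---------------------------------------------------------------------------
# Input sampling and fast simulation


def sample_input(inp: StationaryInput, n: int, dt: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Discretized input trace ``I_0..I_{n-1}`` on a grid of step ``dt``.

    White noise is represented so that ``I_k * dt`` has the correct
    integrated statistics over one bin (``I_k = phi + sigma xi_k /
    sqrt(dt)``).  The OU-correlated input uses its exact Gaussian transition
    kernel (no discretization bias), started from the stationary
    distribution.  Pulse trains are deterministic.
    """
    if inp.kind == "constant":
        return np.full(n, inp.phi)
    if inp.kind == "white":
        return inp.phi + inp.sigma / math.sqrt(dt) * rng.standard_normal(n)
    if inp.kind == "ou_correlated":
        alpha = math.exp(-dt / inp.tau_I)
        innov = inp.sigma_I * math.sqrt(1.0 - alpha * alpha) * rng.standard_normal(n)
        innov[0] = inp.sigma_I * rng.standard_normal()  # stationary start
        dev = lfilter([1.0], [1.0, -alpha], innov)
        return inp.phi + dev
    # pulses
    t = np.arange(n) * dt
    I = np.full(n, inp.phi)
    for i in range(inp.n_pulses):
        on = inp.pulse_start + i * inp.pulse_interval
        I[(t >= on) & (t < on + inp.pulse_width)] += inp.pulse_amplitude
    return I


def _check_dt(dt: float, tau: float, name: str) -> None:
    if dt >= 0.5 * tau:
        raise StepSizeError(f"dt={dt} too large for {name}={tau}; need dt < {name}/2")


def simulate_fast(unit: Unit, state: ControlState, T: float, dt: float,
                  seed: int | np.random.SeedSequence = 0,
                  r0: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the fast variable at frozen control state.

    Returns ``(times, trace)`` where ``trace`` is the rate ``r`` (rate
    units) or the sensor ``rho`` (Poisson/calcium unit).  Rate units use
    Euler-Maruyama; the sensor decays exactly between spike counts drawn
    per bin (thinning with piecewise-constant intensity).  Identical
    ``(unit, state, T, dt, seed)`` give identical trajectories.
    """
    n = int(round(T / dt))
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    s_input, s_intr = ss.spawn(2)
    rng_in = np.random.default_rng(s_input)
    rng_intr = np.random.default_rng(s_intr)
    x, g = state.a, state.b
    t = np.arange(n) * dt

    if isinstance(unit, PoissonCalciumUnit):
        _check_dt(dt, unit.tau_d, "tau_d")
        I = sample_input(unit.input, n, dt, rng_in)
        lam = np.clip(g * I + x, 0.0, None)
        spikes = rng_intr.poisson(lam * dt)
        decay = math.exp(-dt / unit.tau_d)
        rho0 = unit.delta * unit.tau_d * max(g * unit.input.phi + x, 0.0) \
            if r0 is None else r0
        # exact decay between bins, jump at bin end:
        # rho_k = decay * rho_{k-1} + delta * spikes_{k-1}
        u = np.empty(n)
        u[0] = rho0
        u[1:] = unit.delta * spikes[:-1].astype(float)
        rho = lfilter([1.0], [1.0, -decay], u)
        return t, rho

    if isinstance(unit, OURateUnit):
        tau_r, eta, rec = unit.tau_r, unit.eta, 0.0
    else:  # SelfExcitatoryUnit
        tau_r, eta, rec = 1.0, unit.eta, g
        # effective relaxation 1-g can be slow or even unstable (g >= 1);
        # the explicit scheme is still well defined per step
    _check_dt(dt, tau_r, "tau_r")

    I = sample_input(unit.input, n, dt, rng_in)
    drive = (dt / tau_r) * (g * I + x) \
        + (eta * math.sqrt(dt) / tau_r) * rng_intr.standard_normal(n)
    a1 = 1.0 - (1.0 - rec) * dt / tau_r
    if r0 is None:
        r0 = g * unit.input.phi + x if rec == 0.0 else \
            (g * unit.input.phi + x) / max(1.0 - rec, 1e-6)
    # Euler-Maruyama as a linear recursion: r_k = a1 r_{k-1} + drive_{k-1}
    u = np.empty(n)
    u[0] = r0
    u[1:] = drive[:-1]
    r = lfilter([1.0], [1.0, -a1], u)
    return t, r
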