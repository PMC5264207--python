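"""Control-function pairs and the characteristic-moment / stability algebra.

A dual homeostatic control system couples two slow negative-feedback
variables ``a`` and ``b`` to a fast firing rate ``r``::

    (tau_a / eps) da/dt = f_a(r_a) - f_a(r)
    (tau_b / eps) db/dt = f_b(r_b) - f_b(r)

where ``f_a``, ``f_b`` are smooth increasing control functions, ``r_a``,
``r_b`` are target rates, and ``eps`` separates the slow homeostatic time
scale from the fast rate dynamics.  Averaging over the stationary rate
distribution yields a two-dimensional slow ODE whose fixed points are
characterized *purely by the firing-rate mean and variance they enforce*:
when the control functions have constant curvature, every fixed point pins
the rate distribution to a characteristic mean ``mu_star`` and variance
``nu_star`` determined by the targets and the convexity ratios
``K = f''/f'`` alone — independent of the neuron model and of the input
statistics.

This module implements that algebra: convexity ratios, the exact
characteristic moments and their small target-separation approximation,
the averaged drift under a constant-curvature (or Gaussian-closure)
expansion, the inverse map from desired moments back to targets, and the
sign criterion for stability of the averaged fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ControlFunction",
    "DualControlConfig",
    "CharacteristicMoments",
    "InvalidControlFunctionError",
    "DegenerateConvexityError",
    "SingularConfigurationError",
    "UnreachableMomentsError",
    "quadratic",
    "linear",
    "exponential",
    "convexity_ratio",
    "characteristic_moments",
    "characteristic_moments_approx",
    "targets_for_moments",
    "averaged_drift",
    "stability_margin",
]


class InvalidControlFunctionError(ValueError):
    """Control function violates its contract (e.g. f' <= 0 at a target)."""


class DegenerateConvexityError(ValueError):
    """K_a == K_b with distinct targets: nu_star is undefined."""


class SingularConfigurationError(ValueError):
    """The k-denominator K_a - K_b - K_a K_b (r_b - r_a) vanishes."""


class UnreachableMomentsError(ValueError):
    """No target pair in the control functions' domains yields the moments."""


# ---------------------------------------------------------------------------
# Control functions


@dataclass(frozen=True)
class ControlFunction:
    """A smooth increasing map from firing rate to feedback signal.

    Parameters
    ----------
    f, df, d2f
        The function and its first two derivatives, each a scalar (or
        vectorized) callable of rate.
    domain
        Closed rate interval on which the function is valid.
    coeffs
        For members of the canonical quadratic family
        ``f(r) = c0 + c1 r + c2 r**2``, the tuple ``(c0, c1, c2)``.  The
        quadratic family has constant second derivative, which makes the
        characteristic-moment and stability results exact; it is also the
        only family the compiled stochastic kernels accept.
    name
        Purely cosmetic label used in reprs and logs.
    """

    f: Callable[[float], float]
    df: Callable[[float], float]
    d2f: Callable[[float], float]
    domain: tuple[float, float] = (-np.inf, np.inf)
    coeffs: tuple[float, float, float] | None = None
    name: str = "custom"

    def __call__(self, r):
        return self.f(r)

    @property
    def is_quadratic(self) -> bool:
        return self.coeffs is not None

    @property
    def has_constant_curvature(self) -> bool:
        # constant f'' makes the second-order expansion of <f(r)> exact
        return self.coeffs is not None

    def in_domain(self, r: float) -> bool:
        lo, hi = self.domain
        return lo <= r <= hi

    def to_config(self) -> dict:
        if self.coeffs is not None:
            c0, c1, c2 = self.coeffs
            return {"type": "quadratic", "c0": c0, "c1": c1, "c2": c2}
        return {"type": "custom", "name": self.name}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.coeffs is not None:
            c0, c1, c2 = self.coeffs
            return f"ControlFunction(quadratic c0={c0:g}, c1={c1:g}, c2={c2:g})"
        return f"ControlFunction({self.name})"


def quadratic(c0: float = 0.0, c1: float = 0.0, c2: float = 0.0,
              domain: tuple[float, float] = (-np.inf, np.inf)) -> ControlFunction:
    """Member of the canonical family ``f(r) = c0 + c1 r + c2 r**2``.

    The family is increasing on ``r > -c1/(2 c2)`` for ``c2 > 0``; the caller
    is responsible for choosing a domain on which ``f' > 0`` (checked lazily
    wherever a derivative is evaluated).
    """
    c0, c1, c2 = float(c0), float(c1), float(c2)
    return ControlFunction(
        f=lambda r: c0 + c1 * r + c2 * r * r,
        df=lambda r: c1 + 2.0 * c2 * r,
        d2f=lambda r: 2.0 * c2 + 0.0 * r,
        domain=domain,
        coeffs=(c0, c1, c2),
        name="quadratic",
    )


def linear(slope: float = 1.0, intercept: float = 0.0) -> ControlFunction:
    """``f(r) = intercept + slope * r`` — zero curvature, K = 0."""
    return quadratic(intercept, slope, 0.0)


def exponential(scale: float = 1.0) -> ControlFunction:
    """``f(r) = exp(scale * r)`` — constant convexity ratio K = scale.

    Not in the quadratic family: used to exercise the Gaussian-closure path
    (its curvature is not constant, so the second-order expansion of
    ``<f(r)>`` is no longer exact, but ``f''/f'`` is the constant ``scale``).
    """
    s = float(scale)
    return ControlFunction(
        f=lambda r: np.exp(s * r),
        df=lambda r: s * np.exp(s * r),
        d2f=lambda r: s * s * np.exp(s * r),
        name=f"exp({s:g} r)",
    )


# ---------------------------------------------------------------------------
# Configuration and results


@dataclass(frozen=True)
class DualControlConfig:
    """Parameters of a dual homeostatic control system.

    ``tau_a`` and ``tau_b`` are the slow time constants (in seconds of slow
    time); ``epsilon`` is the explicit time-scale separation multiplier, so
    the effective relaxation rates of the slow variables are
    ``epsilon / tau_a`` and ``epsilon / tau_b``.  A mechanism flagged
    multiplicative evolves as ``tau db/dt = b [f_b(r_b) - f_b(r)]`` and is
    integrated in log coordinates so its state stays positive.
    """

    fa: ControlFunction
    fb: ControlFunction
    r_a: float
    r_b: float
    tau_a: float = 100.0
    tau_b: float = 1000.0
    epsilon: float = 1.0
    multiplicative_a: bool = False
    multiplicative_b: bool = True

    def __post_init__(self):
        if not (self.tau_a > 0 and self.tau_b > 0):
            raise ValueError("tau_a and tau_b must be positive")
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must lie in (0, 1]")
        if not self.fa.in_domain(self.r_a):
            raise ValueError(f"target r_a={self.r_a} outside fa domain {self.fa.domain}")
        if not self.fb.in_domain(self.r_b):
            raise ValueError(f"target r_b={self.r_b} outside fb domain {self.fb.domain}")

    def swapped(self) -> "DualControlConfig":
        """Exchange the roles of the two mechanisms (a <-> b)."""
        return DualControlConfig(
            fa=self.fb, fb=self.fa, r_a=self.r_b, r_b=self.r_a,
            tau_a=self.tau_b, tau_b=self.tau_a, epsilon=self.epsilon,
            multiplicative_a=self.multiplicative_b,
            multiplicative_b=self.multiplicative_a,
        )


@dataclass(frozen=True)
class CharacteristicMoments:
    """Characteristic firing-rate mean/variance at averaged fixed points.

    ``nu_star`` may come out negative: a formally negative variance means
    the control system has *no realizable fixed point* (flagged via
    ``realizable`` rather than raised, so phase-diagram sweeps can record
    "no fixed point" regions).
    """

    mu_star: float
    nu_star: float
    K_a: float
    K_b: float
    k: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def realizable(self) -> bool:
        return self.nu_star >= 0.0


# ---------------------------------------------------------------------------
# Operations


def convexity_ratio(f: ControlFunction, r: float) -> float:
    """Curvature measure ``K = f''(r) / f'(r)`` (units 1/rate).

    The relative sizes of the two mechanisms' convexity ratios decide which
    target must be larger for a fixed point to exist, and set the scale of
    the characteristic variance.
    """
    if not f.in_domain(r):
        raise ValueError(f"rate {r} outside control-function domain {f.domain}")
    d1 = float(f.df(r))
    if d1 == 0.0 or not np.isfinite(d1):
        raise InvalidControlFunctionError(
            f"f'({r}) = {d1}; control functions must have nonzero slope")
    if d1 < 0.0:
        raise InvalidControlFunctionError(
            f"f'({r}) = {d1} < 0; control functions must be increasing")
    return float(f.d2f(r)) / d1


def characteristic_moments(cfg: DualControlConfig) -> CharacteristicMoments:
    """Exact characteristic mean and variance of a dual control system.

    With ``K_a = f_a''(r_a)/f_a'(r_a)``, ``K_b = f_b''(r_b)/f_b'(r_b)`` and

        k = (K_a + K_b) / (K_a - K_b - K_a K_b (r_b - r_a))

    the fixed points of the averaged system are exactly the states at which
    the rate distribution attains

        mu_star = (r_a + r_b)/2 + (r_b - r_a)/2 * k
        nu_star = (r_b - r_a)/(K_b - K_a)
                  * (2 - (r_b - r_a)/4 * ((K_b - K_a)(1 + k^2)
                                          - 2 (K_a + K_b) k))

    (exact when both control functions have constant curvature).  The result
    is symmetric under exchanging the two mechanisms.
    """
    K_a = convexity_ratio(cfg.fa, cfg.r_a)
    K_b = convexity_ratio(cfg.fb, cfg.r_b)
    dr = cfg.r_b - cfg.r_a

    if dr == 0.0:
        # zero target separation: the only consistent moments are
        # mean = common target, variance = 0, for any admissible pair
        return CharacteristicMoments(
            mu_star=cfg.r_a, nu_star=0.0, K_a=K_a, K_b=K_b, k=0.0)

    if K_a == K_b:
        raise DegenerateConvexityError(
            "equal convexity ratios with distinct targets: nu_star undefined")

    denom = K_a - K_b - K_a * K_b * dr
    if denom == 0.0:
        raise SingularConfigurationError(
            "k-denominator K_a - K_b - K_a K_b (r_b - r_a) vanishes")

    k = (K_a + K_b) / denom
    mu_star = 0.5 * (cfg.r_a + cfg.r_b) + 0.5 * dr * k
    nu_star = (dr / (K_b - K_a)) * (
        2.0 - 0.25 * dr * ((K_b - K_a) * (1.0 + k * k)
                           - 2.0 * (K_a + K_b) * k))
    return CharacteristicMoments(
        mu_star=float(mu_star), nu_star=float(nu_star),
        K_a=K_a, K_b=K_b, k=float(k))


def characteristic_moments_approx(cfg: DualControlConfig) -> CharacteristicMoments:
    """Small target-separation approximation of the characteristic moments.

        mu_star ~ (r_a + r_b)/2 - (r_b - r_a)/2 * (K_a + K_b)/(K_b - K_a)
        nu_star ~ 2 (r_b - r_a) / (K_b - K_a)

    Valid when ``K |r_b - r_a|`` and ``K^2 |r_b - r_a| / |K_b - K_a|``
    (``K = max(|K_a|, |K_b|)``) are small; both smallness diagnostics are
    returned.  Two practical consequences follow directly: a fixed point can
    exist only when ``r_b - r_a`` and ``K_b - K_a`` share a sign, and the
    characteristic variance grows proportionally to the target separation.
    """
    K_a = convexity_ratio(cfg.fa, cfg.r_a)
    K_b = convexity_ratio(cfg.fb, cfg.r_b)
    dr = cfg.r_b - cfg.r_a

    if dr == 0.0:
        return CharacteristicMoments(
            mu_star=cfg.r_a, nu_star=0.0, K_a=K_a, K_b=K_b, k=0.0,
            diagnostics={"K_dr": 0.0, "K2_dr_over_dK": 0.0})
    if K_a == K_b:
        raise DegenerateConvexityError(
            "equal convexity ratios: corollary approximation undefined")

    K = max(abs(K_a), abs(K_b))
    dK = K_b - K_a
    k_approx = -(K_a + K_b) / dK
    mu_star = 0.5 * (cfg.r_a + cfg.r_b) + 0.5 * dr * k_approx
    nu_star = 2.0 * dr / dK
    return CharacteristicMoments(
        mu_star=float(mu_star), nu_star=float(nu_star),
        K_a=K_a, K_b=K_b, k=float(k_approx),
        diagnostics={"K_dr": K * abs(dr),
                     "K2_dr_over_dK": K * K * abs(dr) / abs(dK)})


def _fixed_point_residual(f: ControlFunction, target: float,
                          mu: float, nu: float) -> float:
    """Residual of the single-mechanism fixed-point equation.

    For constant curvature, ``<f(r)> = f(target)`` is equivalent to

        0 = K nu + 2 (mu - target) + K (mu - target)^2

    with ``K = f''(target)/f'(target)`` (curvature evaluated at the target).
    """
    K = convexity_ratio(f, target)
    d = mu - target
    return K * nu + 2.0 * d + K * d * d


def targets_for_moments(fa: ControlFunction, fb: ControlFunction,
                        mu_star: float, nu_star: float) -> tuple[float, float]:
    """Invert the characteristic-moment map: targets for desired moments.

    Given a desired stationary mean/variance pair, return targets
    ``(r_a, r_b)`` whose characteristic moments reproduce them.  For a
    linear/quadratic pair the closed form ``r_a = mu_star`` and
    ``r_b = sqrt(nu_star + mu_star^2)`` applies; otherwise each target
    solves its own scalar fixed-point equation (the two equations decouple),
    found by bracketing + Brent's method on the control function's domain.
    """
    if nu_star < 0:
        raise UnreachableMomentsError("nu_star must be nonnegative")

    out = []
    for f in (fa, fb):
        # linear control: K == 0 identically -> target = mu_star
        if f.coeffs is not None and f.coeffs[2] == 0.0:
            out.append(float(mu_star))
            continue
        # pure-quadratic-through-origin closed form: r = sqrt(nu + mu^2)
        if (f.coeffs is not None and f.coeffs[1] == 0.0 and f.coeffs[2] != 0.0
                and f.coeffs[2] > 0.0 and nu_star + mu_star ** 2 >= 0.0):
            out.append(float(math.sqrt(nu_star + mu_star ** 2)))
            continue
        out.append(_solve_target(f, mu_star, nu_star))
    return out[0], out[1]


def _solve_target(f: ControlFunction, mu: float, nu: float) -> float:
    lo, hi = f.domain
    # search bracket: centre on mu, expand to a generous multiple of the
    # moment scale, clipped to the domain
    span = 10.0 * (abs(mu) + math.sqrt(max(nu, 0.0)) + 1.0)
    lo = max(lo, mu - span) if np.isfinite(lo) else mu - span
    hi = min(hi, mu + span) if np.isfinite(hi) else mu + span
    grid = np.linspace(lo, hi, 512)
    vals = []
    for r in grid:
        try:
            vals.append(_fixed_point_residual(f, float(r), mu, nu))
        except (InvalidControlFunctionError, ValueError):
            vals.append(np.nan)
    vals = np.asarray(vals)
    ok = np.isfinite(vals)
    idx = np.flatnonzero(ok[:-1] & ok[1:] & (np.sign(vals[:-1]) != np.sign(vals[1:])))
    for i in idx:
        try:
            root = brentq(lambda r: _fixed_point_residual(f, r, mu, nu),
                          grid[i], grid[i + 1], xtol=1e-12, rtol=1e-10)
            return float(root)
        except ValueError:
            continue
    raise UnreachableMomentsError(
        f"no target in {f.domain} reproduces (mu, nu) = ({mu}, {nu}) for {f!r}")


# ---------------------------------------------------------------------------
# Averaged drift


_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss_hermite_mean(f: Callable, mu: float, nu: float, order: int = 64) -> float:
    """``<f(r)>`` under a Gaussian closure r ~ N(mu, nu) by Gauss-Hermite."""
    if nu <= 0.0:
        return float(f(mu))
    if order not in _GH_CACHE:
        x, w = np.polynomial.hermite_e.hermegauss(order)
        _GH_CACHE[order] = (x, w / w.sum())
    x, w = _GH_CACHE[order]
    return float(np.dot(w, f(mu + math.sqrt(nu) * x)))


def averaged_drift(cfg: DualControlConfig, mu: float, nu: float,
                   quad_order: int = 64) -> tuple[float, float]:
    """Averaged feedback drift ``(F_a, F_b)`` at rate moments ``(mu, nu)``.

    ``F_a = f_a(r_a) - <f_a(r)>`` and likewise for ``b``.  For
    constant-curvature control functions the second-order expansion

        <f(r)> = f(r_t) + f'(r_t)(mu - r_t) + 1/2 f''(r_t)(nu + (mu - r_t)^2)

    around the target ``r_t`` is exact; otherwise ``<f(r)>`` is evaluated by
    Gauss-Hermite quadrature under a Gaussian closure of the rate
    distribution.  Both drifts vanish exactly at the characteristic moments.
    """
    if nu < 0:
        raise ValueError("variance must be nonnegative")

    out = []
    for f, target in ((cfg.fa, cfg.r_a), (cfg.fb, cfg.r_b)):
        if f.has_constant_curvature:
            d = mu - target
            mean_f = (float(f.f(target)) + float(f.df(target)) * d
                      + 0.5 * float(f.d2f(target)) * (nu + d * d))
        else:
            mean_f = _gauss_hermite_mean(f.f, mu, nu, quad_order)
        out.append(float(f.f(target)) - mean_f)
    return out[0], out[1]


def stability_margin(surface_point, fa: ControlFunction, fb: ControlFunction,
                     mu_star: float) -> float:
    """Sign criterion for stability of an averaged fixed point.

    Returns the product

        (dmu/da dnu/db - dmu/db dnu/da) * (f_b''(mu*)/f_b'(mu*)
                                           - f_a''(mu*)/f_a'(mu*))

    with the moment-surface partials evaluated at the fixed point
    (``surface_point`` is a :class:`~dualhomeo.neuron_models.SurfacePoint`,
    or any object exposing ``dmu_da``, ``dmu_db``, ``dnu_da``, ``dnu_db``).
    A positive value certifies exponential stability of the averaged fixed
    point, provided each mechanism's self-feedback is negative there (that
    assumption is checked and reported by the fixed-point layer, not here).
    The expression is invariant under exchanging the two mechanisms.  Zero
    means this criterion is silent.
    """
    for attr in ("dmu_da", "dmu_db", "dnu_da", "dnu_db"):
        if not hasattr(surface_point, attr):
            raise TypeError(
                f"surface point lacks partial derivative {attr!r}; "
                "an incomplete surface cannot be tested for stability")
    det = (surface_point.dmu_da * surface_point.dnu_db
           - surface_point.dmu_db * surface_point.dnu_da)
    return float(det * (convexity_ratio(fb, mu_star)
                        - convexity_ratio(fa, mu_star)))
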