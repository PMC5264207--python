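"""Fixed points of the averaged control system and their stability.

Locates control states ``(a*, b*)`` at which a model's stationary moment
surface attains the characteristic mean/variance demanded by the control
configuration, assembles the averaged Jacobian there, classifies stability
by its eigenvalues, and cross-checks the eigenvalue classification against
the sign criterion (moment-surface determinant times the difference of
control-function convexity ratios).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .control_laws import (CharacteristicMoments, DualControlConfig,
                           averaged_drift, characteristic_moments,
                           stability_margin)
from .neuron_models import MomentSurface

__all__ = [
    "FixedPointReport",
    "IncompleteSurfaceError",
    "find_fixed_point",
    "averaged_jacobian",
    "classify_stability",
    "nullclines",
]

logger = logging.getLogger(__name__)


class IncompleteSurfaceError(ValueError):
    """Moment-surface partial derivatives unavailable."""


@dataclass
class FixedPointReport:
    """Everything known about one (attempted) averaged fixed point."""

    status: str                      # "ok" | "none_found"
    moments: CharacteristicMoments
    location: tuple[float, float] | None = None
    surface_moments: tuple[float, float] | None = None
    jacobian: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    stability: str = "none_found"    # stable | unstable | marginal | none_found
    theorem2_margin: float | None = None
    assumption_flags: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "status": self.status,
            "stability": self.stability,
            "mu_star": self.moments.mu_star,
            "nu_star": self.moments.nu_star,
            "theorem2_margin": self.theorem2_margin,
            "assumption_flags": self.assumption_flags,
            "diagnostics": self.diagnostics,
        }
        if self.location is not None:
            d["a_star"], d["b_star"] = self.location
            d["surface_mu"], d["surface_nu"] = self.surface_moments
            d["jacobian"] = self.jacobian.tolist()
            d["eigenvalues_real"] = np.real(self.eigenvalues).tolist()
            d["eigenvalues_imag"] = np.imag(self.eigenvalues).tolist()
        return d


# ---------------------------------------------------------------------------


def _initial_guess(surface: MomentSurface, cfg: DualControlConfig,
                   mu_star: float, nu_star: float) -> tuple[float, float]:
    """Coarse grid seed: scan b, solve the mean equation in a per b,
    keep the b whose variance comes closest to the characteristic one."""
    best, best_err = (mu_star, 1.0), np.inf
    for b in np.geomspace(1e-3, 1e4, 60):
        a = mu_star  # Newton on mu(a, b) = mu_star in a
        ok = True
        for _ in range(12):
            if not surface.in_domain(a, b):
                ok = False
                break
            da = surface.dmu_da(a, b)
            if da == 0:
                ok = False
                break
            step = (surface.mu(a, b) - mu_star) / da
            a -= step
            if abs(step) < 1e-12 * max(abs(a), 1.0):
                break
        if not ok or not surface.in_domain(a, b):
            continue
        err = abs(surface.nu(a, b) - nu_star)
        if err < best_err:
            best, best_err = (a, b), err
    return best


def find_fixed_point(surface: MomentSurface, cfg: DualControlConfig,
                     guess: tuple[float, float] | None = None,
                     tol: float = 1e-10, n_retries: int = 8,
                     max_iter: int = 200) -> FixedPointReport:
    """Solve ``mu(a, b) = mu*``, ``nu(a, b) = nu*`` on a moment surface.

    The characteristic moments come from the control configuration; a
    formally negative characteristic variance, or one below the surface's
    variance floor, means the demanded rate statistics are unreachable and
    the report is ``none_found`` (no exception — phase-diagram sweeps
    record these regions).  The root solve is a damped Newton iteration in
    ``(a, log b)`` when the b-mechanism is multiplicative (so the gain
    stays positive), retried from perturbed starts around the seed.
    """
    moments = characteristic_moments(cfg)
    mu_s, nu_s = moments.mu_star, moments.nu_star
    if nu_s < 0:
        return FixedPointReport(
            status="none_found", moments=moments,
            diagnostics={"reason": "negative characteristic variance"})
    floor = float(surface.nu_floor(mu_s))
    if nu_s < floor - 1e-12:
        return FixedPointReport(
            status="none_found", moments=moments,
            diagnostics={"reason": "characteristic variance below the "
                                   "surface's variance floor",
                         "nu_floor": floor})

    log_b = cfg.multiplicative_b
    seed = guess if guess is not None else _initial_guess(surface, cfg, mu_s, nu_s)
    scale = max(abs(mu_s), math.sqrt(max(nu_s, 0.0)), 1.0)
    rng = np.random.default_rng(0)  # deterministic retry pattern

    starts = [seed]
    for _ in range(n_retries - 1):
        fa = 1.0 + 0.5 * rng.standard_normal()
        fb = math.exp(0.5 * rng.standard_normal())
        starts.append((seed[0] * fa + 0.1 * rng.standard_normal(), seed[1] * fb))

    for a0, b0 in starts:
        if b0 <= 0 and log_b:
            continue
        root = _newton_2d(surface, mu_s, nu_s, a0, b0, log_b, tol, max_iter)
        if root is None:
            continue
        a_st, b_st = root
        if log_b and b_st <= 0:
            continue
        return _build_report(surface, cfg, moments, a_st, b_st)

    return FixedPointReport(
        status="none_found", moments=moments,
        diagnostics={"reason": "solver did not converge from any start",
                     "seed": list(seed), "scale": scale})


def _newton_2d(surface, mu_s, nu_s, a0, b0, log_b, tol, max_iter):
    a, b = float(a0), float(b0)
    if not surface.in_domain(a, b):
        return None
    scale = max(abs(mu_s), abs(nu_s), 1.0)
    for _ in range(max_iter):
        F = np.array([surface.mu(a, b) - mu_s, surface.nu(a, b) - nu_s])
        if np.max(np.abs(F)) < tol * scale:
            return a, b
        J = np.array([[surface.dmu_da(a, b), surface.dmu_db(a, b)],
                      [surface.dnu_da(a, b), surface.dnu_db(a, b)]], float)
        if log_b:
            J[:, 1] *= b  # d/d(log b) = b d/db
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        for _ in range(30):  # damping: backtrack until residual decreases
            if log_b:
                a_n, b_n = a - lam * step[0], b * math.exp(-lam * step[1])
            else:
                a_n, b_n = a - lam * step[0], b - lam * step[1]
            if surface.in_domain(a_n, b_n):
                Fn = np.array([surface.mu(a_n, b_n) - mu_s,
                               surface.nu(a_n, b_n) - nu_s])
                if np.linalg.norm(Fn) < np.linalg.norm(F):
                    a, b = a_n, b_n
                    break
            lam *= 0.5
        else:
            return None
    return None


def _build_report(surface, cfg, moments, a_st, b_st) -> FixedPointReport:
    J = averaged_jacobian(surface, cfg, (a_st, b_st))
    eig = np.linalg.eigvals(J)
    label = classify_stability(J)
    point = surface.at(a_st, b_st)
    margin = stability_margin(point, cfg.fa, cfg.fb, moments.mu_star)
    flags = {
        "negative_self_feedback_a": bool(J[0, 0] < 0),
        "negative_self_feedback_b": bool(J[1, 1] < 0),
    }
    report = FixedPointReport(
        status="ok", moments=moments, location=(a_st, b_st),
        surface_moments=(point.mu, point.nu), jacobian=J, eigenvalues=eig,
        stability=label, theorem2_margin=margin, assumption_flags=flags)
    if all(flags.values()) and margin is not None:
        concordant = ((margin > 0 and label == "stable")
                      or (margin < 0 and label != "stable")
                      or (margin == 0))
        if not concordant:
            # sufficient-condition violation is only possible when the
            # sign criterion's assumptions fail; eigenvalues win
            logger.warning(
                "stability-margin sign (%.3g) disagrees with eigenvalue "
                "classification (%s) at (%.4g, %.4g)",
                margin, label, a_st, b_st)
            report.diagnostics["margin_eigen_discrepancy"] = True
    return report


def averaged_jacobian(surface: MomentSurface, cfg: DualControlConfig,
                      point: tuple[float, float],
                      coords: str = "natural",
                      fd_step: float = 1e-6) -> np.ndarray:
    """Jacobian of the averaged slow ODE at a fixed point.

    For constant-curvature control functions each entry is assembled in
    closed form,

        dF_a/du = -dmu/du f_a'(mu*) - 1/2 f_a''(mu*) dnu/du,

    scaled by the slow rates ``epsilon/tau``; otherwise entries fall back
    to central finite differences of the averaged drift.  ``coords``
    selects the state chart: ``natural`` gives d(a, b)/dt including the
    state factor of any multiplicative mechanism (valid at a fixed point,
    matching the classic linear/quadratic example), ``log`` gives the
    Jacobian in the integration coordinates (a or log a, b or log b).
    """
    a_st, b_st = point
    if not surface.in_domain(a_st, b_st):
        raise ValueError(f"point {point} outside surface domain")
    p = surface.at(a_st, b_st)
    mu_star = p.mu
    rate_a, rate_b = cfg.epsilon / cfg.tau_a, cfg.epsilon / cfg.tau_b

    if cfg.fa.has_constant_curvature and cfg.fb.has_constant_curvature:
        rows = []
        for f in (cfg.fa, cfg.fb):
            d1, d2 = float(f.df(mu_star)), float(f.d2f(mu_star))
            rows.append([-p.dmu_da * d1 - 0.5 * d2 * p.dnu_da,
                         -p.dmu_db * d1 - 0.5 * d2 * p.dnu_db])
        J = np.array(rows, float)
    else:
        J = np.empty((2, 2))
        ha = fd_step * max(abs(a_st), 1.0)
        hb = fd_step * max(abs(b_st), 1.0)
        for col, (da, db, h) in enumerate([(1.0, 0.0, ha), (0.0, 1.0, hb)]):
            pts = [(a_st + h * da, b_st + h * db), (a_st - h * da, b_st - h * db)]
            drifts = []
            for (ai, bi) in pts:
                mu, nu = float(surface.mu(ai, bi)), float(surface.nu(ai, bi))
                drifts.append(averaged_drift(cfg, mu, max(nu, 0.0)))
            J[0, col] = (drifts[0][0] - drifts[1][0]) / (2 * h)
            J[1, col] = (drifts[0][1] - drifts[1][1]) / (2 * h)

    J[0, :] *= rate_a
    J[1, :] *= rate_b
    if coords == "natural":
        if cfg.multiplicative_a:
            J[0, :] *= a_st
        if cfg.multiplicative_b:
            J[1, :] *= b_st
    elif coords == "log":
        if cfg.multiplicative_a:
            J[:, 0] *= a_st
        if cfg.multiplicative_b:
            J[:, 1] *= b_st
    else:
        raise ValueError("coords must be 'natural' or 'log'")
    return J


def classify_stability(jacobian: np.ndarray,
                       tol: float = 1e-8) -> str:
    """Eigenvalue classification of a 2x2 real Jacobian.

    ``stable`` if both real parts are below ``-tol * ||J||``, ``unstable``
    if any is above ``+tol * ||J||``, ``marginal`` inside the band (the
    degenerate constant-input case produces an exact zero eigenvalue along
    its line of fixed points).
    """
    J = np.asarray(jacobian, float)
    if J.shape != (2, 2):
        raise ValueError("jacobian must be 2x2")
    band = tol * max(np.linalg.norm(J), 1e-300)
    re = np.real(np.linalg.eigvals(J))
    if np.all(re < -band):
        return "stable"
    if np.any(re > band):
        return "unstable"
    return "marginal"


def nullclines(surface: MomentSurface, cfg: DualControlConfig,
               a_range: tuple[float, float], b_range: tuple[float, float],
               n: int = 201) -> dict[str, list[np.ndarray]]:
    """Zero-contour polylines of the averaged drifts on an (a, b) grid.

    Returns ``{"a": [...], "b": [...]}``, each entry a list of (m, 2)
    arrays of (a, b) vertices where the corresponding averaged drift
    vanishes.  Intersections of the two families are the averaged fixed
    points (up to grid resolution).  Grid cells outside the surface domain
    are masked out.
    """
    from skimage.measure import find_contours

    a_grid = np.linspace(*a_range, n)
    b_grid = np.linspace(*b_range, n)
    Fa = np.full((n, n), np.nan)
    Fb = np.full((n, n), np.nan)
    for i, a in enumerate(a_grid):
        for j, b in enumerate(b_grid):
            if not surface.in_domain(a, b):
                continue
            mu = float(surface.mu(a, b))
            nu = float(surface.nu(a, b))
            Fa[i, j], Fb[i, j] = averaged_drift(cfg, mu, max(nu, 0.0))

    out: dict[str, list[np.ndarray]] = {"a": [], "b": []}
    da = a_grid[1] - a_grid[0]
    db = b_grid[1] - b_grid[0]
    for key, F in (("a", Fa), ("b", Fb)):
        for contour in find_contours(F, 0.0):
            pts = np.column_stack([a_grid[0] + contour[:, 0] * da,
                                   b_grid[0] + contour[:, 1] * db])
            out[key].append(pts)
    return out
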