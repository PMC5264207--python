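"""Numba inner loops for the coupled slow-fast stochastic simulations.

These kernels are private plumbing: the public API wraps them in
:mod:`dualhomeo.coupled_simulation` and :mod:`dualhomeo.integrator_experiments`.
All kernels are restricted to the canonical quadratic control-function
family ``f(r) = c0 + c1 r + c2 r^2`` (constant curvature, for which the
averaged-theory results are exact) and advance the slow variables with
plain Euler steps; a mechanism flagged multiplicative is advanced in log
coordinates so its state stays positive.

Traces are recorded every ``stride`` steps to bound memory.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _quad(c0, c1, c2, r):
    return c0 + c1 * r + c2 * r * r


@njit(cache=True)
def dual_rate_kernel(I, xi, dt, tau_r, recurrent, eta,
                     a0c, a1c, a2c, fa_target,
                     b0c, b1c, b2c, fb_target,
                     rate_a, rate_b, mult_a, mult_b,
                     r0, x0, g0, stride):
    """Joint Euler(-Maruyama) integration of rate + two slow controls.

    Fast equation: ``tau_r dr = (-r + g*(rec*r + I) + x) dt + eta dW`` with
    ``rec`` 1 for the self-excitatory unit and 0 for the plain rate unit.
    ``rate_a = epsilon/tau_a`` and ``rate_b = epsilon/tau_b`` are the slow
    relaxation rates; ``fa_target = f_a(r_a)`` etc. are precomputed.
    Returns (r, a, b) traces sampled every ``stride`` steps (the final
    state is appended as the last sample).
    """
    n = I.shape[0]
    m = n // stride + 1
    r_out = np.empty(m)
    a_out = np.empty(m)
    b_out = np.empty(m)
    r, a, b = r0, x0, g0
    sq = np.sqrt(dt)
    j = 0
    for k in range(n):
        if k % stride == 0:
            r_out[j] = r
            a_out[j] = a
            b_out[j] = b
            j += 1
        rec_term = r if recurrent else 0.0
        r = r + (dt / tau_r) * (-r + b * (rec_term + I[k]) + a) \
            + (eta * sq / tau_r) * xi[k]
        da = rate_a * dt * (fa_target - _quad(a0c, a1c, a2c, r))
        db = rate_b * dt * (fb_target - _quad(b0c, b1c, b2c, r))
        if mult_a:
            a = a * np.exp(da)
        else:
            a = a + da
        if mult_b:
            b = b * np.exp(db)
        else:
            b = b + db
    r_out[j] = r
    a_out[j] = a
    b_out[j] = b
    return r_out[:j + 1], a_out[:j + 1], b_out[:j + 1]


@njit(cache=True)
def dual_poisson_kernel(I, dt, tau_d, delta, seed,
                        a0c, a1c, a2c, fa_target,
                        b0c, b1c, b2c, fb_target,
                        rate_a, rate_b, mult_a, mult_b,
                        rho0, x0, g0, stride):
    """Jump-decay sensor coupled to two slow controls.

    Spikes are drawn per bin as Poisson with piecewise-constant intensity
    ``max(0, g I + x) dt`` (thinning-exact for the clamped intensity); the
    sensor decays exactly between bins and jumps by ``delta`` per spike.
    The slow controls are driven by the sensor value ``rho``.
    """
    np.random.seed(seed)
    n = I.shape[0]
    m = n // stride + 1
    r_out = np.empty(m)
    a_out = np.empty(m)
    b_out = np.empty(m)
    rho, a, b = rho0, x0, g0
    decay = np.exp(-dt / tau_d)
    j = 0
    for k in range(n):
        if k % stride == 0:
            r_out[j] = rho
            a_out[j] = a
            b_out[j] = b
            j += 1
        lam = b * I[k] + a
        if lam < 0.0:
            lam = 0.0
        s = np.random.poisson(lam * dt)
        rho = rho * decay + delta * s
        da = rate_a * dt * (fa_target - _quad(a0c, a1c, a2c, rho))
        db = rate_b * dt * (fb_target - _quad(b0c, b1c, b2c, rho))
        if mult_a:
            a = a * np.exp(da)
        else:
            a = a + da
        if mult_b:
            b = b * np.exp(db)
        else:
            b = b + db
    r_out[j] = rho
    a_out[j] = a
    b_out[j] = b
    return r_out[:j + 1], a_out[:j + 1], b_out[:j + 1]


@njit(cache=True)
def network_kernel(I_shared, I_ext, dt, eta, seed,
                   a0c, a1c, a2c, fa_targets,
                   b0c, b1c, b2c, fb_targets,
                   rate_a, rate_b, mult_b,
                   r_init, x_init, g_init, stride):
    """Mean-field recurrent excitatory network with per-unit dual control.

    Unit i obeys ``dr_i = (-r_i + g_i (rbar + I(t)) + x_i + I_ext(t)) dt
    + eta dW_i`` with ``rbar`` the population-mean rate (time rescaled,
    tau_r = 1); ``I_ext`` is an injected current that bypasses the
    synaptic gain (used by the pulse tests).
    Each unit runs its own dual homeostasis toward its own targets
    ``fa_targets[i] = f_a(r_a,i)``; private noise streams are generated
    in-kernel from ``seed``.  Set ``rate_a = rate_b = 0`` to freeze
    homeostasis (e.g. during pulse tests).

    Returns (rbar trace, r, x, g traces of shape (m, N)).
    """
    np.random.seed(seed)
    n = I_shared.shape[0]
    N = r_init.shape[0]
    m = n // stride + 1
    rbar_out = np.empty(m)
    r_out = np.empty((m, N))
    x_out = np.empty((m, N))
    g_out = np.empty((m, N))
    r = r_init.copy()
    x = x_init.copy()
    g = g_init.copy()
    sq = np.sqrt(dt)
    j = 0
    for k in range(n):
        rbar = 0.0
        for i in range(N):
            rbar += r[i]
        rbar /= N
        if k % stride == 0:
            rbar_out[j] = rbar
            for i in range(N):
                r_out[j, i] = r[i]
                x_out[j, i] = x[i]
                g_out[j, i] = g[i]
            j += 1
        for i in range(N):
            r[i] = r[i] + dt * (-r[i] + g[i] * (rbar + I_shared[k]) + x[i]
                                + I_ext[k]) \
                + eta * sq * np.random.standard_normal()
            if rate_a != 0.0 or rate_b != 0.0:
                da = rate_a * dt * (fa_targets[i] - _quad(a0c, a1c, a2c, r[i]))
                db = rate_b * dt * (fb_targets[i] - _quad(b0c, b1c, b2c, r[i]))
                x[i] = x[i] + da
                if mult_b:
                    g[i] = g[i] * np.exp(db)
                else:
                    g[i] = g[i] + db
    rbar = 0.0
    for i in range(N):
        rbar += r[i]
    rbar /= N
    rbar_out[j] = rbar
    for i in range(N):
        r_out[j, i] = r[i]
        x_out[j, i] = x[i]
        g_out[j, i] = g[i]
    return rbar_out[:j + 1], r_out[:j + 1], x_out[:j + 1], g_out[:j + 1]
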