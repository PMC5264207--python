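# Methods

## Model and assumptions

The package studies a fast scalar observable `r` (a firing rate, or a
calcium-like correlate of it) coupled to two slow feedback variables `a`
and `b`:

```
(tau_a / eps) da/dt = f_a(r_a) - f_a(r)
(tau_b / eps) db/dt = f_b(r_b) - f_b(r)
```

`f_a`, `f_b` are smooth increasing control functions; `r_a`, `r_b` are the
rates at which each mechanism is silent in isolation.  A mechanism flagged
*multiplicative* (the synaptic gain `g` in the canonical interpretation)
carries an extra state factor, `tau db/dt = b [...]`, and is integrated in
log coordinates, which keeps it positive and makes the extra factor
irrelevant to the fixed-point structure.

The analysis assumes the fast variable is distribution-ergodic at frozen
`(a, b)`: over times long against its relaxation time, time averages equal
expectations under a stationary distribution with mean `mu(a, b)` and
variance `nu(a, b)` (the *moment surface*).  Averaging the slow equations
over that distribution gives the deterministic averaged system whose drift
is `F = f(target) − ⟨f(r)⟩`.

Two exact results drive everything else, both valid when the control
functions have constant second derivative:

1. Fixed points of the averaged system are exactly the states where the
   rate distribution attains a characteristic mean `mu*` and variance
   `nu*` that depend only on the targets and the convexity ratios
   `K = f''/f'` at the targets.  `nu*` can be formally negative, in which
   case no fixed point exists; the package returns it with a `realizable`
   flag rather than raising, so parameter sweeps can chart "no fixed
   point" regions.
2. A fixed point is exponentially stable (given negative self-feedback of
   each mechanism) when the moment-surface determinant
   `dmu/da dnu/db − dmu/db dnu/da` and the convexity difference
   `K_b(mu*) − K_a(mu*)` have the same sign.  The package evaluates this
   margin and, independently, the eigenvalues of the averaged Jacobian;
   when the two disagree — possible only where the margin's assumptions
   fail, since the criterion is sufficient, not necessary — the eigenvalue
   classification wins and the discrepancy is logged.

The canonical control-function family is quadratic,
`f(r) = c0 + c1 r + c2 r²`, for which `f''` is constant and both results
are exact.  General smooth functions are admitted in the analytic layer:
`⟨f(r)⟩` is then evaluated under a Gaussian closure of the rate
distribution by Gauss–Hermite quadrature (64 nodes by default), an
approximation that is exact for Gaussian-rate models such as the linear
units and a robustness check elsewhere.

## Neuron models

* **Linear (OU) rate unit** `tau_r dr = (−r + g I(t) + x) dt + eta dW`:
  `mu = g phi + x`, `nu = (g² C + eta²)/(2 tau_r)`.  `C` summarizes the
  input autocovariance seen through the rate filter and is defined
  operationally as the constant making the input-driven variance
  `g² C/(2 tau_r)`: `C = 0` for constant input, `C = sigma²` for white
  input of amplitude `sigma`, and
  `C = 2 tau_r sigma_I² tau_I/(tau_I + tau_r)` for an
  Ornstein–Uhlenbeck-correlated input (the printed double-integral form of
  this constant has ambiguous typeset limits, so the closed form is used
  and a slow numerical double integration is kept as a cross-check; both
  are validated against long simulations).  Variance floor:
  `eta²/(2 tau_r)`.
* **Poisson spiker with calcium sensor**: spikes are Poisson with
  intensity `g I(t) + x` clamped at zero; the sensor `rho` jumps by
  `delta` per spike and decays with `tau_d`.  Stationary sensor moments
  `mu = delta tau_d (g phi + x)`,
  `nu = delta² tau_d (C g² + (g phi + x)/2)`; the shot-noise term imposes
  the reachability floor `nu ≥ delta·mu/2`.  (The printed partial
  `dnu/dg` of this model carries a sign typo; the implementation
  differentiates the printed `nu` itself, which also reproduces the
  printed determinant `2 delta³ tau_d² C g`.)
* **Self-excitatory unit** `dr = (−r + g(r + I) + x) dt + eta dW` (time
  rescaled so `tau_r = 1`), valid for `g < 1`: `mu = (g phi + x)/(1−g)`,
  `nu = (g² C + eta²)/(2(1−g))`.  The variance is strictly increasing in
  `g` and diverges at 1, so demanding a large characteristic variance
  forces the gain toward the integrator point.  Partials are the exact
  derivatives of these expressions.

Rate variables are allowed to go negative in the linear models (no
rectification); only the Poisson intensity is clamped.

## Numerical methods

* **Fast simulation at frozen controls** (`simulate_fast`): rate units use
  Euler–Maruyama written as a linear recursion and evaluated by
  `scipy.signal.lfilter`; the calcium sensor decays exactly between bins
  with per-bin Poisson spike counts (thinning with piecewise-constant
  intensity, exact for the clamped intensity).  The OU-correlated input is
  generated with its exact Gaussian transition kernel from a stationary
  start, eliminating discretization bias in the `C` validation.
* **Coupled slow-fast simulation** (`simulate_dual`): a joint Euler step
  for fast and slow variables in compiled (numba) kernels, restricted to
  the quadratic control family; multiplicative mechanisms advance in log
  coordinates.  One seed per run; input noise and intrinsic noise draw
  from independent substreams of it, so trajectories are bit-reproducible
  for identical (config, seed, dt).  The Euler step biases the stationary
  variance of an OU unit by `2 tau_r/(2 tau_r − dt)`; default step sizes
  (dt = tau_r/50) keep this near 1%.
* **Averaged ODE** (`simulate_averaged`): `scipy.integrate.solve_ivp`
  (LSODA, rtol 1e−9) on `(a, log b)`; leaving the surface domain (e.g.
  the Poisson intensity turning non-positive) stops integration with a
  `domain_exit` outcome instead of an exception.
* **Fixed-point location**: damped Newton on
  `(mu − mu*, nu − nu*) = 0` in `(a, log b)`, seeded by a coarse scan over
  `b` with a 1-D mean-equation solve per `b`, with 8 deterministic retry
  starts; tolerance 1e−10 relative.  Characteristic variances below the
  surface's floor short-circuit to `none_found`.  The `g = 0` boundary
  family is excluded rather than characterized.
* **Inverse target map** (`targets_for_moments`): the two fixed-point
  equations decouple into one scalar equation per mechanism; linear and
  pure-quadratic controls use closed forms, anything else a bracketed
  Brent solve on the function's domain.
* **Empirical moments**: batch means (20 batches) over the post-burn-in
  window give autocorrelation-aware standard errors; the window must cover
  at least 100 fast relaxation times.
* **Outcome classification** operationalizes qualitative regimes:
  *wind-up* = `|a|` beyond 10× its initial scale with consistent drift
  direction on 16-segment coarse-grained means of the final half (checked
  first — the strong-noise failure mode shows wind-up of `a` and collapse
  of `b` simultaneously); *synapse elimination* = `b` below 1e−3 of its
  initial value; *converged* = over the final quarter the `(a, b)`
  trajectory stays within a ball of radius 0.5× the state scale **and**
  the two halves of that window have centers closer than half the observed
  spread (no net drift).  Everything else is `undetermined` — in
  particular a trajectory trapped in a wide neighborhood whose
  correlations outlast the window, which is bounded but not certifiably
  stationary.
* **Nullclines**: zero contours of the averaged drifts on a rectangular
  grid, extracted with `skimage.measure.find_contours`.

## Integrator experiments

Pulse tests inject rectangular current pulses *directly* into the rate
equation (bypassing the synaptic gain, as a current-injection probe; the
baseline input still arrives synaptically — a purely synaptic probe would
leave a `g = 0` unit silent and its leak unmeasurable).  Homeostasis is
frozen during the test, and intrinsic noise is off by default so the probe
measures the deterministic leak of the frozen state.  The metrics:

* `retention_ratio` = (rate at next pulse onset − resting rate)/(rate at
  pulse offset − resting rate), averaged over pulses.  For a linear unit
  with leak `lam` this equals `exp(−lam·gap)` for every pulse; a ratio of
  increments would instead go to zero as the pulse train saturates, even
  for a slow leak.  Verdict `integrator` at retention ≥ 0.8.
* `effective_leak` = −slope of regressing `dr/dt` on `r` over the
  inter-pulse gaps; for the single unit it estimates `(1−g)/tau_r`.

`tune_then_test` probes the unit before homeostasis, runs the coupled
simulation, takes the tuned state as the mean of the final tenth of the
slow trajectory (smoothing residual slow fluctuation), and probes again.
The heterogeneous network couples N units through the population-mean rate
(`mean-field`; each unit receives `g_i (rbar + I)`), with per-unit targets
drawn so every unit demands a large characteristic variance
(`nu*_i` uniform in [40, 80] by default) and per-unit homeostasis running
concurrently.  N = 1 reduces exactly to the single unit.  The default
N = 20 is a desk-scale stand-in for a few-hundred-neuron network; the
construction accepts any N.

## Parameter choices

Printed setup values are used where they exist: input mean `phi = 1`,
white-noise variance `sigma² = 0.001` and targets 2.5/3.5 for the
canonical convergence scenario; `tau_I = 10 s` for the correlated-input
scenario; `eta² = 5`, `C = 1` for the integrator unit.  Slow time
constants for the figure-level scenarios live in appendices not available
here, so the package sets `tau_x = 100 s`, `tau_g = 1000 s` against
`tau_r = 0.1 s` (separation ≥ 10³) as config-exposed defaults, with two
deliberate exceptions: the correlated-input scenario uses
`tau_x = 500 s` / `tau_g = 50 000 s` (slow variables must also be slow
against the 10 s input correlation, and weaker separation lets input
excursions kick the gain into collapse), and the integrator tuning uses
`tau_x = 1000 s` / `tau_g = 10 000 s` (near `g ≈ 0.95` the fast
correlation time is `1/(1−g) ≈ 20`, so the default constants would leave
only ~5× separation and the gain fluctuates by ±0.25 instead of ±0.07).
The strong-intrinsic-noise failure scenario gives the intrinsic mechanism
a convex control (`f_x = r + 0.2 r²`): with a linear `f_x` the intrinsic
mechanism always equilibrates and strong noise produces only synapse
elimination, whereas curvature makes the intrinsic equation insoluble once
the noise floor exceeds `1/K_x²`, reproducing unbounded intrinsic wind-up
alongside the gain collapse.

## What the simulations do and do not show

The synthetic inputs (white, OU-correlated, pulse trains) exercise the
theory's assumptions — second-order stationarity, ergodicity, time-scale
separation — under exactly the conditions where the averaged analysis is
meant to apply.  Passing tests therefore validate the control theory and
its implementation, not biological realism: real synaptic input is neither
Gaussian nor stationary on all time scales, real neurons rectify and
saturate, and the linear rate units have no spiking nonlinearity (only the
Poisson/calcium model has event noise).  Results with marginal time-scale
separation (correlated input, near-integrator gains) depend visibly on the
chosen constants, as the bounded-but-wandering trajectories of the
correlated-input scenario show.

## Known limitations

* Stochastic kernels accept only the quadratic control family; general
  smooth controls are limited to the analytic layer and the averaged ODE.
* The stability margin for non-constant `f''` is implemented as the same
  sign expression plus the numerical eigenvalue cross-check; the analytic
  tolerance bound for strongly varying curvature is not reproduced.
* The network treatment is empirical (reduced-N simulation); no analytic
  claims are made about which units dominate integration.
* `classify_outcome` is a heuristic over finite trajectories; genuinely
  slow transients are reported as `undetermined` rather than guessed.
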