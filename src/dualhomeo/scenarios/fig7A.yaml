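# Self-excitatory unit, eta^2 = 5, C = 1: targets set for a large
# characteristic variance (nu* = 60) park the gain near 1, turning the
# unit into an integrator (pulse-test retention >= 0.8 after tuning).
name: fig7A
experiment: integrator
expected_outcome: integrator
model:
  type: self_excitatory
  eta: 2.23606797749979
  input: {kind: white, phi: 1.0, sigma: 1.0}
control:
  fa: {type: quadratic, c1: 1.0}
  fb: {type: quadratic, c2: 1.0}
  r_a: 2.5
  r_b: 8.139410298049853
  tau_a: 1000.0
  tau_b: 10000.0
run:
  T: 30000.0
  dt: 0.02
  seed: 0
  init: {a: 0.0, b: 0.2}
protocol:
  n_pulses: 5
  amplitude: 5.0
  width: 0.5
  interval: 3.0
  baseline: 1.0
  settle: 20.0
  T_homeo: 30000.0
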