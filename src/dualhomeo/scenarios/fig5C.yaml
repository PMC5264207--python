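# Strong intrinsic noise eta = 10: the variance floor eta^2/(2 tau_r) = 100
# exceeds the characteristic variance, no fixed point exists, and the
# convex intrinsic mechanism winds up without bound while g collapses.
name: fig5C
experiment: simulate
expected_outcome: windup
model:
  type: ou
  tau_r: 0.5
  eta: 10.0
  input: {kind: white, phi: 1.0, sigma: 1.0}
control:
  fa: {type: quadratic, c1: 1.0, c2: 0.2}
  fb: {type: quadratic, c2: 1.0}
  r_a: 2.5
  r_b: 3.5
  tau_a: 100.0
  tau_b: 1000.0
run:
  T: 90.0
  dt: 0.005
  seed: 0
  init: {a: 0.5, b: 1.0}
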