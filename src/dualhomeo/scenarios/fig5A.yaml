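# Intrinsic noise eta = 2 below the tolerance limit: the characteristic
# variance 6 exceeds the floor eta^2/(2 tau_r) = 4, so homeostasis
# converges to the fixed point.
name: fig5A
experiment: simulate
expected_outcome: converged
model:
  type: ou
  tau_r: 0.5
  eta: 2.0
  input: {kind: white, phi: 1.0, sigma: 1.0}
control:
  fa: {type: quadratic, c1: 1.0}
  fb: {type: quadratic, c2: 1.0}
  r_a: 2.5
  r_b: 3.5
  tau_a: 100.0
  tau_b: 1000.0
run:
  T: 24000.0
  dt: 0.005
  seed: 0
  init: {a: 1.0, b: 1.35}
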