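# White-noise input (sigma^2 = 0.001), linear/quadratic controls,
# r_x = 2.5 < r_g = 3.5: convergence to the homeostatic fixed point with
# characteristic mean 2.5 and variance 3.5^2 - 2.5^2 = 6.
name: fig2A
experiment: simulate
expected_outcome: converged
model:
  type: ou
  tau_r: 0.1
  input: {kind: white, phi: 1.0, sigma: 0.03162277660168379}
control:
  fa: {type: quadratic, c1: 1.0}
  fb: {type: quadratic, c2: 1.0}
  r_a: 2.5
  r_b: 3.5
  tau_a: 100.0
  tau_b: 1000.0
run:
  T: 12000.0
  dt: 0.002
  seed: 1
  init: {a: -28.677, b: 31.177}
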