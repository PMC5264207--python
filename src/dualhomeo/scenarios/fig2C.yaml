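# Control functions exchanged (x quadratically controlled, g linearly):
# a fixed point exists at the same characteristic moments but is unstable.
name: fig2C
experiment: simulate
expected_outcome: divergence
model:
  type: ou
  tau_r: 0.1
  input: {kind: white, phi: 1.0, sigma: 0.03162277660168379}
control:
  fa: {type: quadratic, c2: 1.0}
  fb: {type: quadratic, c1: 1.0}
  r_a: 3.5
  r_b: 2.5
  tau_a: 100.0
  tau_b: 1000.0
run:
  T: 20000.0
  dt: 0.002
  seed: 0
  init: {a: -31.9, b: 34.3}
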