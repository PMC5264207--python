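# White-noise input with reversed targets (r_x = 3.5 > r_g = 2.5):
# the nullclines do not cross and the synaptic gain collapses to zero.
name: fig2B
experiment: simulate
expected_outcome: synapse_elimination
model:
  type: ou
  tau_r: 0.1
  input: {kind: white, phi: 1.0, sigma: 0.03162277660168379}
control:
  fa: {type: quadratic, c1: 1.0}
  fb: {type: quadratic, c2: 1.0}
  r_a: 3.5
  r_b: 2.5
  tau_a: 100.0
  tau_b: 1000.0
run:
  T: 9000.0
  dt: 0.002
  seed: 0
  init: {a: 1.0, b: 2.0}
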