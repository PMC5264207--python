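# Temporally correlated (OU) input, tau_I = 10 s: trajectories fluctuate
# widely but remain inside a bounded neighborhood of the averaged fixed
# point (outcome may report undetermined; boundedness is the claim).
name: fig4CD
experiment: simulate
expected_outcome: bounded
model:
  type: ou
  tau_r: 0.1
  input: {kind: ou_correlated, phi: 1.0, sigma_I: 0.0711, tau_I: 10.0}
control:
  fa: {type: quadratic, c1: 1.0}
  fb: {type: quadratic, c2: 1.0}
  r_a: 2.5
  r_b: 3.5
  tau_a: 500.0
  tau_b: 50000.0
run:
  T: 60000.0
  dt: 0.002
  seed: 0
  init: {a: -31.5, b: 34.5}
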