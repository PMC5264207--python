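# Constant input, intrinsic target above synaptic target: synapse elimination.
name: fig1B
experiment: averaged
expected_outcome: synapse_elimination
model:
  type: ou
  tau_r: 0.1
  input: {kind: constant, phi: 1.0}
control:
  fa: {type: quadratic, c1: 1.0}
  fb: {type: quadratic, c2: 1.0}
  r_a: 3.5
  r_b: 2.5
  tau_a: 100.0
  tau_b: 1000.0
run:
  T: 120000.0
  dt: 0.002
  seed: 0
  init: {a: 1.0, b: 1.0}
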