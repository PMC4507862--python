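# Relative-entropy coarse-graining of the LJ-like toy fluid
# (reduced units: sigma = eps = k_B = 1)
system:
  kind: lj_fluid
  n: 60
  rho: 0.45
  temperature: 1.0
  seed: 0
sampler:
  n_steps: 100000
  stride: 250
  equilibration: 0.25
  max_disp: 0.35
method:
  name: re
  r_cut: 1.8
  dr: 0.1
  chi: 1.0
  tol: 1.0e-4
  max_iter: 10
  window: 5
  seed: 1000
output: out/re_lj
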