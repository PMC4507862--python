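# Targeted (downhill-simplex) coarse-graining of the LJ-like toy fluid
# with the 6-parameter CKDg analytic form, RDF-only penalty (a = 0)
system:
  kind: lj_fluid
  n: 60
  rho: 0.45
  temperature: 1.0
  seed: 0
sampler:
  n_steps: 40000
  stride: 200
  max_disp: 0.35
method:
  name: simplex
  sigma: 1.0
  eps: 1.0
  w_c: 0.5
  h: 0.1
  p: 1.3
  s: 0.2
  spread: 0.2
  max_steps: 25
  relax_steps: 2000
  pressure_weight: 0.0
  seed: 7
output: out/simplex_lj
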