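# Mapping-power scenario: 200 F2 plants, extreme 10% pools, a single
# major additive QTL at 36 cM on chromosome 2.
population:
  type: F2
  size: 200
selection:
  fraction: 0.10
model:
  preset: 1
  env_sd: 1.0
  reps_per_line: 3
map:
  lengths_cM: [135, 88, 101, 125, 139]
  marker_spacing_cM: 0.5
replicates: 200
span: 0.25
seed: 7
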