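# Isolation growth: NP strain on OP50, unlimited resource,
# no density mortality, no predation; started with 50 juveniles.
version: 1
seed: 0
scenario:
  id: fig1f_np_op50
  m: 1
  layout: {kind: homogeneous, diet: OP50}
  seeding:
    kind: explicit
    entries: [{x: 1, y: 1, strain: NP, stage: J, count: 50}]
  toggles: {predation: false, density_mortality: false, resource_limitation: false}
  max_steps: 1500
  record_every: 10
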