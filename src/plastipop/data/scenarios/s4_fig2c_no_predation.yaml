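# 20x20 lattice, homogeneous OP50, corner-seeded competition with
# intraguild predation and dauer dispersal r = 0.01.
version: 1
seed: 0
scenario:
  id: s4_fig2c_no_predation
  m: 20
  layout: {kind: homogeneous, diet: OP50}
  seeding: {kind: default}
  toggles: {predation: false, density_mortality: true, resource_limitation: true}
  max_steps: 12000
  record_every: 100
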