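# Well-mixed competition (m=1), finite resource, density mortality,
# predation ON, diet OP50; both strains seeded with 50 dauer larvae.
version: 1
seed: 0
scenario:
  id: fig2a_pred_on_l76
  m: 1
  layout: {kind: homogeneous, diet: L76}
  seeding:
    kind: explicit
    entries:
      - {x: 1, y: 1, strain: P, stage: D, count: 50}
      - {x: 1, y: 1, strain: NP, stage: D, count: 50}
  toggles: {predation: true, density_mortality: true, resource_limitation: true}
  max_steps: 6000
  record_every: 10
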