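# Boom-bust: resources replenished every 1000 steps with random diet
# reassignment; random initial layout and seed locations.
version: 1
seed: 0
scenario:
  id: fig4
  m: 20
  layout: {kind: random}
  seeding: {kind: random}
  replenishment: {interval: 1000, reassign_diets: true}
  max_steps: 10000
  record_every: 100
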