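# Random diet assignment per deme and randomized seed locations.
version: 1
seed: 7
scenario:
  id: s6_fig3c_alt
  m: 20
  layout: {kind: random}
  seeding: {kind: random}
  max_steps: 12000
  record_every: 100
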