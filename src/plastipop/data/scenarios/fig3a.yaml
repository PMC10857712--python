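# Quadrant resource layout, pattern A: the plastic-seeded corners
# (S[1,1], S[m,m]) sit in OP50 quadrants, the non-plastic-seeded corners
# in L76 quadrants.
version: 1
seed: 0
scenario:
  id: fig3a
  m: 20
  layout: {kind: quadrants, pattern: A}
  seeding: {kind: default}
  max_steps: 12000
  record_every: 100
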