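# Quadrant resource layout, pattern B: the plastic-seeded corners
# (S[1,1], S[m,m]) sit in L76 quadrants, the non-plastic-seeded corners
# in OP50 quadrants.
version: 1
seed: 0
scenario:
  id: fig3b
  m: 20
  layout: {kind: quadrants, pattern: B}
  seeding: {kind: default}
  max_steps: 12000
  record_every: 100
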