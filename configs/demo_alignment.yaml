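# Demonstration alignment: 8 conserved segments between neutral spacers on
# the 12-leaf demo tree, with planted events:
#   - segment 0 accelerated (r=8) in hibernator lineages hib_A and hib_B
#     (a parallel accelerated element)
#   - segment 4 accelerated (r=8) in hib_C only
#   - segment 6 deleted in hib_D
n_conserved: 8
conserved_len: 150
neutral_len: 600
rho: 0.3
accelerated:
  - {index: 0, r: 8.0, lineages: [hib_A, hib_B]}
  - {index: 4, r: 8.0, lineages: [hib_C]}
deleted:
  - {index: 6, lineages: [hib_D]}
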