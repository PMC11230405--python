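# Demonstration motif sequences: 100 sequences with one planted instance of
# the built-in demonstration motif, 100 background sequences, 200 bp each.
n_with: 100
n_without: 100
seq_len: 200
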