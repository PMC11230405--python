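# Demonstration expression matrix: 300 genes x 60 samples with three planted
# 50-gene modules (graded loadings 1.0 down to 0.5) and noise sd 0.3.
n_genes: 300
n_samples: 60
noise_sd: 0.3
modules:
  - {size: 50}
  - {size: 50}
  - {size: 50}
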