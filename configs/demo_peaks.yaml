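# Demonstration peak replicates: 50 true peaks, 8 replicates, 20% dropout,
# up to 25 bp of boundary jitter.
n_peaks: 50
spacing: 2000
peak_width: 400
n_reps: 8
dropout: 0.2
jitter: 25
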