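# Demonstration contact map: 120 x 10 kb bins, 5 promoter bins, elements in
# bins 100-104 with 4x planted contact enrichment over the 5% base rate.
n_bins: 120
bin_size: 10000
promoter_bins: [10, 30, 50, 70, 90]
element_positions: [1005000, 1015000, 1025000, 1035000, 1045000]
enrichment_factor: 4.0
base_contact_prob: 0.05
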