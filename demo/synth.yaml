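n_drugs: 12
n_proteins: 8
drug_len_range: [16, 40]
protein_len_range: [40, 90]
noise_sd: 0.15
seed: 11
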