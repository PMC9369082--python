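drug_branch:
  max_len: 48
  kernel_size: 4
  n_heads: 2
  head_depth: 2
  embed_dim: 16
  base_filters: 8
  batchnorm_everywhere: true
protein_branch:
  max_len: 96
  kernel_size: 6
  n_heads: 2
  head_depth: 2
  embed_dim: 16
  base_filters: 8
  batchnorm_everywhere: true
dense_sizes: [64, 64, 32]
optimizer_name: adam
learning_rate: 0.002
batch_size: 16
epochs: 6
early_stop_patience: 5
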