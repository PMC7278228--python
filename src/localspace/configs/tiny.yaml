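# Scaled-down configuration for CPU smoke runs and offline benchmarks.
generator:
  n_layers: 2
  hidden_units: 64
  dropout_keep: 0.8
  learning_rate: 0.003
  grad_clip_norm: 5.0
  n_streams: 8
  chunk_len: 16
  vocab_size: 37
training:
  pretrain_epochs: 15
  log_every: 10
  n_variants: 4
sampling:
  token_budget: 2000
screening:
  epochs_round1: 30
  epochs_later: 20
  sample_every: 10
  tokens_per_sample: 2000
  retain_fraction: 0.5
  k_clusters: 7
  n_variants: 10
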