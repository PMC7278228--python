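# Full-scale protocol configuration: 2 stacked LSTM layers, 512 hidden
# units (use 256 for directly trained models), dropout keep 0.8, Adam lr
# 0.003, gradient-norm clip 5, 128 streams x 64 steps, 200,000-token
# sampling, 50 pretraining epochs, 30/20 fine-tuning epochs sampling every
# 10, top-50% retention, 7 cluster catalogs.
generator:
  n_layers: 2
  hidden_units: 512
  dropout_keep: 0.8
  learning_rate: 0.003
  grad_clip_norm: 5.0
  n_streams: 128
  chunk_len: 64
  vocab_size: 37
training:
  pretrain_epochs: 50
  log_every: 200
  n_variants: 10
sampling:
  token_budget: 200000
screening:
  epochs_round1: 30
  epochs_later: 20
  sample_every: 10
  tokens_per_sample: 200000
  retain_fraction: 0.5
  k_clusters: 7
  n_variants: 10
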