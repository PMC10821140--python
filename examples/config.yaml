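# Example configuration: desk-scale settings for every training stage.
# Omitted keys fall back to the full-scale defaults (256-dim, batch 16/128,
# 100 epochs, patience 10). Unknown keys are rejected.

contrastive:
  embed_dim: 64
  encoder_layers: 2
  attention_heads: 2
  ff_dim: 128
  proj_hidden_dim: 64
  proj_out_dim: 32
  temperature: 0.1
  batch_molecules: 16
  max_epochs: 10
  patience: 5
  learning_rate: 0.002
  max_len: 80

generator:
  n_blocks: 2
  d_model: 64
  d_ff: 128
  attention_heads: 2
  max_len: 80
  dropout: 0.0
  learning_rate: 0.002
  batch_size: 64
  max_epochs: 30
  patience: 10

cpi:
  d_model: 32
  d_ff: 64
  n_layers: 1
  attention_heads: 2
  dropout: 0.0
  smiles_max_len: 80
  protein_max_len: 100
  batch_size: 128
  learning_rate: 0.002
  max_epochs: 8
  patience: 8
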