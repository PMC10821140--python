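# contramol

Contrastive representation learning over enumerated SMILES writings, with
transfer of the learned token embedding into (a) an autoregressive
transformer decoder for de-novo molecule generation and (b) a dual-encoder
compound–protein interaction (CPI) classifier, plus the full evaluation
layer (validity / uniqueness / novelty / success rate / internal diversity,
molecular property profiling, precision / recall / F1).

The neural stacks (transformer encoder/decoder, NT-Xent loss, AdamW) are
implemented on a small numpy reverse-mode autodiff engine in
`contramol.nn`, so the package runs on a plain scientific-Python stack
with no deep-learning framework. Everything is desk-scale: toy corpora
generated by `contramol.fixtures` stand in for the large public datasets.

## Layout

- `contramol.smiles` — validation, canonicalization, randomized
  enumeration (atom-order shuffling before the DFS writer), regex
  tokenizer, vocabularies, `.smi`/CSV I/O.
- `contramol.nn` — autograd engine, transformer blocks, AdamW,
  checkpoint container.
- `contramol.contrastive` — encoder + projection head, NT-Xent loss,
  pre-training loop, embedding extraction.
- `contramol.generator` — decoder-only LM, exact-GELU feed-forward
  blocks, frozen/unfrozen embedding transfer, multinomial & beam sampling.
- `contramol.cpi` — dual-encoder interaction classifier and TSV I/O.
- `contramol.metrics` — generation metrics, Tanimoto / internal
  diversity, QED / SAScore / LogP / TPSA / MW profiling, classification
  metrics, distribution comparison.
- `contramol.fixtures` — toy drug-like SMILES corpora, planted-signal
  CPI tables, lead-like filters (MW 250–350, LogP ≤ 3.5, length ≤ 100),
  seeded ratio splits (19:1, 8:1:1).
- `contramol.reference_data` — published benchmark rows and case-study
  SMILES used by the regression/acceptance suites.

## CLI

```bash
contramol fixtures --kind smiles -n 2000 --seed 0 --out corpus.smi
contramol filter --in corpus.smi --out lead_like.smi
contramol split --in corpus.smi --ratios 19:1 --seed 0 --out-prefix part
contramol pretrain --corpus corpus.smi --config cfg.yaml --seed 0 --out pre.ckpt
contramol train-gen --corpus corpus.smi --config cfg.yaml \
    --embedding pre.ckpt --freeze --seed 0 --out gen.ckpt
contramol generate --ckpt gen.ckpt -n 500 --strategy multinomial --seed 0 --out samples.smi
contramol evaluate --generated samples.smi --training corpus.smi --out report.json
contramol fixtures --kind cpi -n 2000 --seed 0 --out cpi.tsv
contramol train-cpi --data cpi.tsv --config cfg.yaml --seed 0 --out cpi.ckpt
contramol eval-cpi --ckpt cpi.ckpt --data cpi.tsv --out cpi_report.json
```

Configs are a single YAML document with `contrastive` / `generator` /
`cpi` sections; unknown keys are rejected. All randomness flows from the
`--seed` flag.

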