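"""Dual-encoder compound-protein interaction classifier.

One transformer encoder reads the molecule SMILES, another reads the
amino-acid sequence; their mean-pooled outputs are concatenated and mapped
by a single linear layer to two interaction logits.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import contrastive
from .metrics import ClassificationMetrics, classification_metrics
from .nn import (
    AdamW,
    Checkpoint,
    CheckpointError,
    Linear,
    Module,
    Tensor,
    concatenate,
    cross_entropy,
    mean_pool,
    TransformerStack,
)
from .smiles import (
    DEFAULT_MAX_LEN,
    SPECIALS,
    TokenVocabulary,
    pad_batch,
    tokenize,
    validate_smiles,
)
from .fixtures import SplitSpec, split_dataset

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_VOCAB = TokenVocabulary(tokens=SPECIALS + tuple(AMINO_ACIDS))


@dataclass(frozen=True)
class CPIRecord:
    smiles: str
    protein: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not self.protein:
            raise ValueError("protein sequence must be non-empty")
        if not validate_smiles(self.smiles):
            raise ValueError(f"invalid SMILES: {self.smiles!r}")


@dataclass
class CPIConfig:
    d_model: int = 256
    d_ff: int = 1024
    n_layers: int = 4
    attention_heads: int = 8
    dropout: float = 0.0
    smiles_max_len: int = DEFAULT_MAX_LEN
    protein_max_len: int = 1000
    batch_size: int = 128
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 10
    # keep the best-validation checkpoint (standard) or the final epoch
    # (useful for permutation-test nulls, where "best" is degenerate)
    restore_best: bool = True

    def validate(self):
        if self.n_layers < 1 or self.attention_heads < 1:
            raise ValueError("layers and heads must be >= 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")


def tokenize_protein(seq: str, max_len: int) -> "np.ndarray":
    """One token per amino-acid letter, unknown letters -> unk; truncated
    (not an error) beyond max_len - 2 residues."""
    body = [PROTEIN_VOCAB.id_of(ch) for ch in seq[: max_len - 2]]
    return (PROTEIN_VOCAB.bos_id, *body, PROTEIN_VOCAB.eos_id)


class CPIModel(Module):
    def __init__(self, mol_vocab_size: int, config: CPIConfig,
                 rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        common = dict(d_model=config.d_model, d_ff=config.d_ff,
                      n_layers=config.n_layers, n_heads=config.attention_heads,
                      rng=rng, causal=False, dropout=config.dropout)
        self.mol_encoder = TransformerStack(
            vocab_size=mol_vocab_size, max_len=config.smiles_max_len, **common
        )
        self.prot_encoder = TransformerStack(
            vocab_size=PROTEIN_VOCAB.size, max_len=config.protein_max_len, **common
        )
        self.head = Linear(2 * config.d_model, 2, rng)
        self.frozen_params: set[str] = set()

    def forward(self, mol_ids, mol_mask, prot_ids, prot_mask,
                drop_rng=None) -> Tensor:
        mol = mean_pool(self.mol_encoder(mol_ids, mol_mask, drop_rng=drop_rng),
                        mol_mask)
        prot = mean_pool(self.prot_encoder(prot_ids, prot_mask, drop_rng=drop_rng),
                         prot_mask)
        return self.head(concatenate([mol, prot], axis=-1))


def _encode_batch(records: list[CPIRecord], vocab: TokenVocabulary,
                  config: CPIConfig):
    from .smiles import TokenizedSequence

    mol_seqs = [tokenize(r.smiles, vocab, config.smiles_max_len) for r in records]
    prot_seqs = [TokenizedSequence(ids=tokenize_protein(r.protein, config.protein_max_len))
                 for r in records]
    mol_ids, mol_mask = pad_batch(mol_seqs)
    prot_ids, prot_mask = pad_batch(prot_seqs)
    labels = np.array([r.label for r in records], dtype=np.int64)
    return mol_ids, mol_mask, prot_ids, prot_mask, labels


def cpi_forward(model: CPIModel, records: list[CPIRecord],
                vocab: TokenVocabulary) -> np.ndarray:
    """Inference-mode interaction logits, (batch, 2)."""
    mol_ids, mol_mask, prot_ids, prot_mask, _ = _encode_batch(
        records, vocab, model.config
    )
    return model.forward(mol_ids, mol_mask, prot_ids, prot_mask).data


def _predict(model, records, vocab, batch_size=256) -> np.ndarray:
    preds = []
    for start in range(0, len(records), batch_size):
        logits = cpi_forward(model, records[start:start + batch_size], vocab)
        preds.append(logits.argmax(axis=-1))
    return np.concatenate(preds)


def train(dataset: list[CPIRecord], config: CPIConfig,
          embedding: tuple[Checkpoint, bool] | None = None,
          seed: int = 0, log=sys.stderr) -> Checkpoint:
    """8:1:1 split, cross-entropy with AdamW, early stopping on validation
    loss; optional contrastive-embedding transfer into the molecule encoder."""
    config.validate()
    if len(dataset) < 10:
        raise ValueError("dataset too small for an 8:1:1 split")
    train_set, val_set, test_set = split_dataset(
        dataset, SplitSpec(ratios=(8, 1, 1), seed=seed)
    )
    vocab = TokenVocabulary.build([r.smiles for r in dataset])
    if embedding is not None:
        _, ckpt_vocab = contrastive.extract_embedding(embedding[0])
        missing = set(vocab.tokens) - set(ckpt_vocab.tokens)
        if missing:
            raise CheckpointError(
                f"checkpoint vocabulary lacks dataset tokens: {sorted(missing)}"
            )
        vocab = ckpt_vocab
    rng = np.random.default_rng(seed)
    model = CPIModel(vocab.size, config, rng)
    if embedding is not None:
        table, _ = contrastive.extract_embedding(embedding[0])
        if table.shape[1] != config.d_model:
            raise CheckpointError("embedding dim does not match d_model")
        model.mol_encoder.tok_emb.weight.data = table.copy()
        if embedding[1]:
            model.frozen_params.add("mol_encoder.tok_emb.weight")

    opt = AdamW(model.named_parameters(), lr=config.learning_rate)
    opt.freeze(model.frozen_params)
    best_val, best_state, best_epoch = np.inf, model.state_dict(), 0
    stale = 0
    history = []
    for epoch in range(1, config.max_epochs + 1):
        epoch_rng = np.random.default_rng(seed + 1000 * epoch)
        order = epoch_rng.permutation(len(train_set))
        train_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            mol_ids, mol_mask, prot_ids, prot_mask, labels = _encode_batch(
                batch, vocab, config
            )
            logits = model.forward(mol_ids, mol_mask, prot_ids, prot_mask,
                                   drop_rng=epoch_rng)
            loss = cross_entropy(logits, labels)
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_losses.append(float(loss.data))
        val_losses = []
        for start in range(0, len(val_set), config.batch_size):
            batch = val_set[start:start + config.batch_size]
            mol_ids, mol_mask, prot_ids, prot_mask, labels = _encode_batch(
                batch, vocab, config
            )
            logits = model.forward(mol_ids, mol_mask, prot_ids, prot_mask)
            val_losses.append(float(cross_entropy(logits, labels).data))
        train_loss = float(np.mean(train_losses))
        val_loss = float(np.mean(val_losses))
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "lr": config.learning_rate})
        if log is not None:
            print(f"epoch {epoch} train {train_loss:.4f} val {val_loss:.4f}",
                  file=log)
        if val_loss < best_val:
            best_val, best_state, best_epoch = val_loss, model.state_dict(), epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    final_state = best_state if config.restore_best else model.state_dict()
    model.load_state_dict(final_state)
    test_pred = _predict(model, test_set, vocab)
    return Checkpoint(
        kind="cpi", state=final_state, config=asdict(config),
        vocab_tokens=list(vocab.tokens),
        protein_vocab_tokens=list(PROTEIN_VOCAB.tokens),
        metadata={
            "seed": seed, "epochs_run": len(history), "best_epoch": best_epoch,
            "best_val_loss": best_val, "history": history,
            "frozen": sorted(model.frozen_params),
            "test_predictions": test_pred.tolist(),
            "test_labels": [r.label for r in test_set],
        },
    )


def load_model(ckpt: Checkpoint) -> tuple[CPIModel, TokenVocabulary]:
    if ckpt.kind != "cpi":
        raise CheckpointError(f"expected a cpi checkpoint, got {ckpt.kind!r}")
    vocab = TokenVocabulary(tokens=tuple(ckpt.vocab_tokens))
    config = CPIConfig(**ckpt.config)
    model = CPIModel(vocab.size, config, np.random.default_rng(0))
    model.load_state_dict(ckpt.state)
    return model, vocab


def evaluate(ckpt: Checkpoint, dataset: list[CPIRecord]) -> ClassificationMetrics:
    """Confusion counts at the argmax decision, then precision/recall/F1."""
    if not dataset:
        raise ValueError("empty evaluation dataset")
    model, vocab = load_model(ckpt)
    preds = _predict(model, dataset, vocab)
    labels = np.array([r.label for r in dataset])
    tp = int(((preds == 1) & (labels == 1)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    return classification_metrics(tp, fp, fn, tn)


# -- TSV I/O -------------------------------------------------------------------

def read_cpi_tsv(path: str | Path) -> list[CPIRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"smiles", "sequence", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"CPI TSV must have columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        seq = str(row.sequence).strip().upper()
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"protein sequence has letters outside the "
                             f"20-letter alphabet: {sorted(bad)}")
        records.append(CPIRecord(smiles=str(row.smiles).strip(), protein=seq,
                                 label=int(row.label)))
    return records


def write_cpi_tsv(records: list[CPIRecord], path: str | Path):
    pd.DataFrame(
        {"smiles": [r.smiles for r in records],
         "sequence": [r.protein for r in records],
         "label": [r.label for r in records]}
    ).to_csv(path, sep="\t", index=False)
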