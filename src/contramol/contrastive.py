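"""Contrastive pre-training over enumerated SMILES views.

A shared token embedding + transformer encoder f(.) pools each view to a
fixed vector r; a two-layer ReLU projection head g(.) maps r to z; the
normalized temperature-scaled cross-entropy (NT-Xent) loss pulls the two
views of one molecule together against the 2(N-1) in-batch negatives.
The trained token-embedding table is the transferable artifact.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, asdict

import numpy as np

from .nn import AdamW, Checkpoint, CheckpointError, Linear, Module, Tensor, TransformerStack, mean_pool
from .smiles import (
    DEFAULT_MAX_LEN,
    MoleculeRecord,
    TokenVocabulary,
    enumerate_smiles,
    pad_batch,
    tokenize,
)


@dataclass
class ContrastiveConfig:
    embed_dim: int = 256
    encoder_layers: int = 4
    attention_heads: int = 8
    ff_dim: int = 1024
    proj_hidden_dim: int = 256
    proj_out_dim: int = 128
    temperature: float = 0.1
    batch_molecules: int = 16
    max_epochs: int = 100
    patience: int = 10
    learning_rate: float = 1e-3
    max_len: int = DEFAULT_MAX_LEN
    validation_fraction: float = 0.05  # 19:1 split of the pre-training corpus

    # grid used when the learning rate is searched rather than fixed
    lr_grid: tuple[float, ...] = (1e-4, 3e-4, 1e-3, 3e-3, 1e-2)

    def validate(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name in ("embed_dim", "encoder_layers", "attention_heads",
                     "proj_hidden_dim", "proj_out_dim", "batch_molecules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


class ContrastiveModel(Module):
    def __init__(self, vocab_size: int, config: ContrastiveConfig,
                 rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        self.encoder = TransformerStack(
            vocab_size=vocab_size, d_model=config.embed_dim,
            d_ff=config.ff_dim, n_layers=config.encoder_layers,
            n_heads=config.attention_heads, max_len=config.max_len,
            rng=rng, causal=False,
        )
        self.proj_hidden = Linear(config.embed_dim, config.proj_hidden_dim, rng)
        self.proj_out = Linear(config.proj_hidden_dim, config.proj_out_dim, rng)

    def encode_views(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """Pooled latent representation r, one row per view; padding-invariant."""
        return mean_pool(self.encoder(ids, mask), mask)

    def project(self, r: Tensor) -> Tensor:
        """z = linear2(ReLU(linear1(r)))."""
        return self.proj_out(self.proj_hidden(r).relu())

    def forward(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        return self.project(self.encode_views(ids, mask))


def cosine_similarity(zi: np.ndarray, zj: np.ndarray) -> float:
    zi, zj = np.asarray(zi, float), np.asarray(zj, float)
    ni, nj = np.linalg.norm(zi), np.linalg.norm(zj)
    if ni == 0 or nj == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(zi @ zj / (ni * nj))


def nt_xent_loss(z: Tensor | np.ndarray, temperature: float) -> Tensor:
    """Mean over all 2N anchors of -log( exp(sim(i,partner)/tau) /
    sum_{k != i} exp(sim(i,k)/tau) ). Rows must be laid out so that
    (2m, 2m+1) are the two views of molecule m."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not isinstance(z, Tensor):
        z = Tensor(z)
    two_n = z.shape[0]
    if two_n == 0 or two_n % 2:
        raise ValueError("batch must contain 2N views, N >= 1")
    norms = (z * z).sum(axis=-1, keepdims=True) ** 0.5
    if np.any(norms.data == 0):
        raise ValueError("zero-norm projection vector")
    zn = z / norms
    sim = zn @ zn.transpose(1, 0)  # (2N, 2N) cosine similarities
    logits = sim * (1.0 / temperature)
    diag_mask = np.where(np.eye(two_n, dtype=bool), -1e9, 0.0)
    logits = logits + Tensor(diag_mask)
    partner = np.arange(two_n) ^ 1  # 0<->1, 2<->3, ...
    shifted = logits - logits.data.max(axis=-1, keepdims=True)
    logz = shifted.exp().sum(axis=-1).log()
    return (logz - shifted.gather_last(partner)).mean()


def make_view_batches(records: list[MoleculeRecord], vocab: TokenVocabulary,
                      batch_molecules: int, max_len: int,
                      rng: np.random.Generator, shuffle: bool = True):
    """Enumerate a fresh view pair per molecule and group into batches of
    2*batch_molecules interleaved views."""
    order = rng.permutation(len(records)) if shuffle else np.arange(len(records))
    batches = []
    for start in range(0, len(order), batch_molecules):
        chunk = order[start:start + batch_molecules]
        if len(chunk) < 2:
            continue  # a single molecule has no in-batch negatives
        seqs = []
        for idx in chunk:
            views = enumerate_smiles(
                records[idx].canonical, 2, int(rng.integers(2 ** 31))
            )
            for v in views:
                seqs.append(tokenize(v, vocab, max_len))
        ids, mask = pad_batch(seqs)
        batches.append((ids, mask))
    return batches


def pretrain(corpus: list[MoleculeRecord], config: ContrastiveConfig,
             seed: int, log=sys.stderr) -> Checkpoint:
    """Full pre-training loop with per-epoch view resampling, AdamW and
    early stopping on a fixed validation view set."""
    config.validate()
    records = [r for r in corpus if r.is_valid]
    if not records:
        raise ValueError("corpus contains no valid molecules")
    vocab = TokenVocabulary.build([r.canonical for r in records])
    rng = np.random.default_rng(seed)
    model = ContrastiveModel(vocab.size, config, rng)

    n_val = max(1, int(round(len(records) * config.validation_fraction)))
    order = rng.permutation(len(records))
    val_records = [records[i] for i in order[:n_val]]
    train_records = [records[i] for i in order[n_val:]]
    if len(train_records) < 2:
        raise ValueError("corpus too small to pre-train")

    # validation pairs fixed across epochs for comparable losses
    val_rng = np.random.default_rng(seed + 1)
    val_batches = make_view_batches(
        val_records, vocab, config.batch_molecules, config.max_len,
        val_rng, shuffle=False,
    )

    opt = AdamW(model.named_parameters(), lr=config.learning_rate)
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    epochs_without_improvement = 0
    history = []
    for epoch in range(1, config.max_epochs + 1):
        epoch_rng = np.random.default_rng(seed + 1000 * epoch)
        train_losses = []
        for ids, mask in make_view_batches(
            train_records, vocab, config.batch_molecules, config.max_len,
            epoch_rng,
        ):
            loss = nt_xent_loss(model.forward(ids, mask), config.temperature)
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_losses.append(float(loss.data))
        val_losses = [
            float(nt_xent_loss(model.forward(ids, mask), config.temperature).data)
            for ids, mask in val_batches
        ]
        train_loss = float(np.mean(train_losses))
        val_loss = float(np.mean(val_losses)) if val_losses else train_loss
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "lr": config.learning_rate})
        if log is not None:
            print(f"epoch {epoch} train {train_loss:.4f} val {val_loss:.4f} "
                  f"lr {config.learning_rate}", file=log)
        if val_loss < best_val:
            best_val, best_state, best_epoch = val_loss, model.state_dict(), epoch
            epochs_without_improvement = 0
        else:
            epochs_without_improvement += 1
            if epochs_without_improvement >= config.patience:
                break
    return Checkpoint(
        kind="contrastive", state=best_state, config=asdict(config),
        vocab_tokens=list(vocab.tokens),
        metadata={"seed": seed, "epochs_run": len(history),
                  "best_epoch": best_epoch, "best_val_loss": best_val,
                  "history": history},
    )


def grid_search_learning_rate(corpus: list[MoleculeRecord],
                              config: ContrastiveConfig, seed: int,
                              log=sys.stderr) -> tuple[Checkpoint, float]:
    """Pre-train once per grid learning rate; return the checkpoint with the
    best validation loss and the winning rate."""
    best = None
    for lr in config.lr_grid:
        cfg = ContrastiveConfig(**{**asdict(config), "learning_rate": lr})
        ckpt = pretrain(corpus, cfg, seed, log=log)
        score = ckpt.metadata["best_val_loss"]
        if best is None or score < best[0]:
            best = (score, ckpt, lr)
    return best[1], best[2]


def load_model(ckpt: Checkpoint) -> tuple[ContrastiveModel, TokenVocabulary]:
    if ckpt.kind != "contrastive":
        raise CheckpointError(f"expected a contrastive checkpoint, got {ckpt.kind!r}")
    vocab = TokenVocabulary(tokens=tuple(ckpt.vocab_tokens))
    config = ContrastiveConfig(**{
        k: tuple(v) if k == "lr_grid" else v for k, v in ckpt.config.items()
    })
    model = ContrastiveModel(vocab.size, config, np.random.default_rng(0))
    model.load_state_dict(ckpt.state)
    return model, vocab


def extract_embedding(ckpt: Checkpoint) -> tuple[np.ndarray, TokenVocabulary]:
    """Token-embedding table and its vocabulary, ready for transfer."""
    if ckpt.kind != "contrastive":
        raise CheckpointError(f"expected a contrastive checkpoint, got {ckpt.kind!r}")
    key = "encoder.tok_emb.weight"
    if key not in ckpt.state:
        raise CheckpointError("checkpoint has no token-embedding table")
    vocab = TokenVocabulary(tokens=tuple(ckpt.vocab_tokens))
    table = np.asarray(ckpt.state[key])
    if table.shape[0] != vocab.size:
        raise CheckpointError("embedding row count does not match vocabulary size")
    return table.copy(), vocab
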