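"""Autoregressive transformer decoder over SMILES tokens.

Each block is masked self-attention followed by a position-wise feed-forward
net (d_model -> d_ff, GELU, d_ff -> d_model). The token-embedding table can
be replaced by a pre-trained contrastive table, frozen or trainable.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import norm

from . import contrastive
from .nn import AdamW, Checkpoint, CheckpointError, Linear, Module, Tensor, TransformerStack, cross_entropy
from .smiles import (
    DEFAULT_MAX_LEN,
    MoleculeRecord,
    TokenVocabulary,
    detokenize,
    enumerate_smiles,
    pad_batch,
    tokenize,
)


def gelu(x: float) -> float:
    """Exact Gaussian error linear unit: x * Phi(x), Phi the N(0,1) CDF."""
    return float(x) * float(norm.cdf(x))


@dataclass
class DecoderConfig:
    n_blocks: int = 8
    d_model: int = 256
    d_ff: int = 1024
    attention_heads: int = 8
    max_len: int = DEFAULT_MAX_LEN
    dropout: float = 0.1
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # per-epoch multiplicative decay
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.05
    # train each epoch on a freshly enumerated (randomized) writing of every
    # molecule instead of the fixed canonical one
    augment: bool = False

    def validate(self):
        if self.d_ff <= self.d_model:
            raise ValueError("d_ff must exceed d_model")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")


@dataclass(frozen=True)
class GeneratedSet:
    smiles: tuple[str, ...]
    seed: int
    strategy: str


class GeneratorModel(Module):
    def __init__(self, vocab_size: int, config: DecoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        self.decoder = TransformerStack(
            vocab_size=vocab_size, d_model=config.d_model, d_ff=config.d_ff,
            n_layers=config.n_blocks, n_heads=config.attention_heads,
            max_len=config.max_len, rng=rng, causal=True,
            dropout=config.dropout,
        )
        self.lm_head = Linear(config.d_model, vocab_size, rng)
        self.frozen_params: set[str] = set()

    def forward(self, ids: np.ndarray, mask: np.ndarray,
                drop_rng: np.random.Generator | None = None) -> Tensor:
        """Next-token logits, (batch, positions, vocab)."""
        return self.lm_head(self.decoder(ids, mask, drop_rng=drop_rng))


def decoder_forward(model: GeneratorModel, ids: np.ndarray,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Inference-mode logits as a plain array (no dropout, no graph)."""
    if mask is None:
        mask = np.ones_like(ids, dtype=bool)
    return model.forward(ids, mask).data


def load_pretrained_embedding(model: GeneratorModel, ckpt: Checkpoint,
                              vocab: TokenVocabulary, freeze: bool) -> GeneratorModel:
    """Replace the decoder's token-embedding table with the contrastive one.

    The checkpoint vocabulary must be identical to the generator vocabulary;
    on mismatch the model is left unmodified.
    """
    table, ckpt_vocab = contrastive.extract_embedding(ckpt)
    if tuple(ckpt_vocab.tokens) != tuple(vocab.tokens):
        raise CheckpointError(
            "checkpoint vocabulary does not match the generator vocabulary"
        )
    emb = model.decoder.tok_emb.weight
    if table.shape[1] != emb.data.shape[1]:
        raise CheckpointError(
            f"embedding dim {table.shape[1]} != decoder d_model {emb.data.shape[1]}"
        )
    emb.data = table.copy()
    if freeze:
        model.frozen_params.add("decoder.tok_emb.weight")
    else:
        model.frozen_params.discard("decoder.tok_emb.weight")
    return model


def _lm_batches(seqs, batch_size, rng, shuffle=True):
    order = rng.permutation(len(seqs)) if shuffle else np.arange(len(seqs))
    for start in range(0, len(order), batch_size):
        chunk = [seqs[i] for i in order[start:start + batch_size]]
        ids, mask = pad_batch(chunk)
        yield ids, mask


def _lm_loss(model: GeneratorModel, ids: np.ndarray, mask: np.ndarray,
             drop_rng=None) -> Tensor:
    inputs, targets = ids[:, :-1], ids[:, 1:]
    in_mask = mask[:, :-1]
    logits = model.forward(inputs, in_mask, drop_rng=drop_rng)
    return cross_entropy(logits, targets, weight_mask=mask[:, 1:])


def train(corpus: list[MoleculeRecord], config: DecoderConfig,
          embedding: tuple[Checkpoint, bool] | None = None,
          seed: int = 0, log=sys.stderr) -> Checkpoint:
    """Next-token cross-entropy training with AdamW and early stopping.

    `embedding` transfers a contrastive checkpoint's table, `(ckpt, freeze)`.
    """
    config.validate()
    records = [r for r in corpus if r.is_valid]
    if not records:
        raise ValueError("corpus contains no valid molecules")
    vocab = TokenVocabulary.build([r.canonical for r in records])
    if embedding is not None:
        # adopt the checkpoint vocabulary so the transfer is well-defined
        _, ckpt_vocab = contrastive.extract_embedding(embedding[0])
        missing = set(vocab.tokens) - set(ckpt_vocab.tokens)
        if missing:
            raise CheckpointError(
                f"checkpoint vocabulary lacks corpus tokens: {sorted(missing)}"
            )
        vocab = ckpt_vocab
    rng = np.random.default_rng(seed)
    model = GeneratorModel(vocab.size, config, rng)
    if embedding is not None:
        load_pretrained_embedding(model, embedding[0], vocab, freeze=embedding[1])

    seqs = [tokenize(r.canonical, vocab, config.max_len) for r in records]
    n_val = max(1, int(round(len(seqs) * config.validation_fraction)))
    order = rng.permutation(len(seqs))
    val_seqs = [seqs[i] for i in order[:n_val]]
    train_seqs = [seqs[i] for i in order[n_val:]]
    train_records = [records[i] for i in order[n_val:]]
    if not train_seqs:
        raise ValueError("corpus too small to train")

    def epoch_sequences(epoch_rng):
        """Canonical writings, or a fresh randomized writing per molecule."""
        if not config.augment:
            return train_seqs
        out = []
        for rec in train_records:
            writing = enumerate_smiles(
                rec.canonical, 1, int(epoch_rng.integers(2 ** 31))
            )[0]
            try:
                seq = tokenize(writing, vocab, config.max_len)
                if vocab.unk_id in seq.ids:  # writing used an unseen token
                    seq = tokenize(rec.canonical, vocab, config.max_len)
            except ValueError:  # randomized writing exceeded max_len
                seq = tokenize(rec.canonical, vocab, config.max_len)
            out.append(seq)
        return out

    opt = AdamW(model.named_parameters(), lr=config.learning_rate)
    opt.freeze(model.frozen_params)
    best_val, best_state, best_epoch = np.inf, model.state_dict(), 0
    stale = 0
    history = []
    for epoch in range(1, config.max_epochs + 1):
        epoch_rng = np.random.default_rng(seed + 1000 * epoch)
        train_losses = []
        for ids, mask in _lm_batches(epoch_sequences(epoch_rng),
                                     config.batch_size, epoch_rng):
            loss = _lm_loss(model, ids, mask, drop_rng=epoch_rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_losses.append(float(loss.data))
        val_losses = [
            float(_lm_loss(model, ids, mask).data)
            for ids, mask in _lm_batches(val_seqs, config.batch_size,
                                         epoch_rng, shuffle=False)
        ]
        train_loss = float(np.mean(train_losses))
        val_loss = float(np.mean(val_losses))
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "lr": opt.lr})
        if log is not None:
            print(f"epoch {epoch} train {train_loss:.4f} val {val_loss:.4f} "
                  f"lr {opt.lr:.2e}", file=log)
        opt.lr *= config.lr_decay
        if val_loss < best_val:
            best_val, best_state, best_epoch = val_loss, model.state_dict(), epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return Checkpoint(
        kind="generator", state=best_state, config=asdict(config),
        vocab_tokens=list(vocab.tokens),
        metadata={"seed": seed, "epochs_run": len(history),
                  "best_epoch": best_epoch, "best_val_loss": best_val,
                  "frozen": sorted(model.frozen_params), "history": history},
    )


def load_model(ckpt: Checkpoint) -> tuple[GeneratorModel, TokenVocabulary]:
    if ckpt.kind != "generator":
        raise CheckpointError(f"expected a generator checkpoint, got {ckpt.kind!r}")
    vocab = TokenVocabulary(tokens=tuple(ckpt.vocab_tokens))
    config = DecoderConfig(**ckpt.config)
    model = GeneratorModel(vocab.size, config, np.random.default_rng(0))
    model.load_state_dict(ckpt.state)
    return model, vocab


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _sample_multinomial(model, vocab, n, temperature, seed):
    rng = np.random.default_rng(seed)
    max_len = model.config.max_len
    ids = np.full((n, 1), vocab.bos_id, dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    while ids.shape[1] < max_len and not done.all():
        mask = np.ones_like(ids, dtype=bool)
        logits = model.forward(ids, mask).data[:, -1, :]
        if temperature != 1.0:
            logits = logits / temperature
        probs = _softmax_rows(logits)
        cdf = probs.cumsum(axis=-1)
        u = rng.random((n, 1))
        nxt = (u < cdf).argmax(axis=-1)
        nxt = np.where(done, vocab.pad_id, nxt)
        done |= nxt == vocab.eos_id
        ids = np.concatenate([ids, nxt[:, None]], axis=1)
    return [detokenize(row.tolist(), vocab) for row in ids]


def _beam_search(model, vocab, n, width, seed):  # noqa: ARG001 (deterministic)
    if width < n:
        width = n
    max_len = model.config.max_len
    beams = [((vocab.bos_id,), 0.0)]
    completed: list[tuple[tuple[int, ...], float]] = []
    while beams and len(completed) < width and len(beams[0][0]) < max_len:
        ids = np.array([b[0] for b in beams], dtype=np.int64)
        mask = np.ones_like(ids, dtype=bool)
        logits = model.forward(ids, mask).data[:, -1, :]
        logprobs = np.log(_softmax_rows(logits) + 1e-300)
        candidates = []
        for (seq, score), row in zip(beams, logprobs):
            top = np.argsort(row)[::-1][: 2 * width]
            for tok in top:
                candidates.append((seq + (int(tok),), score + float(row[tok])))
        candidates.sort(key=lambda c: -c[1])
        beams = []
        for seq, score in candidates:
            if seq[-1] == vocab.eos_id:
                completed.append((seq, score))
            else:
                beams.append((seq, score))
            if len(beams) >= width:
                break
    completed.extend(beams)  # unfinished beams rank by score too
    completed.sort(key=lambda c: -c[1])
    return [detokenize(list(seq), vocab) for seq, _ in completed[:n]]


def sample(ckpt: Checkpoint, n: int, strategy: str = "multinomial",
           temperature: float = 1.0, beam_width: int | None = None,
           seed: int = 0) -> GeneratedSet:
    """Draw `n` raw strings. `multinomial` is seeded and temperature-scaled;
    `beam` returns the top-n completed beams by total log-probability."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model, vocab = load_model(ckpt)
    if strategy == "multinomial":
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        smiles = _sample_multinomial(model, vocab, n, temperature, seed)
        desc = f"multinomial(temperature={temperature})"
    elif strategy == "beam":
        width = beam_width if beam_width is not None else n
        if width < 1:
            raise ValueError("beam width must be >= 1")
        smiles = _beam_search(model, vocab, n, width, seed)
        desc = f"beam(width={width})"
    else:
        raise ValueError(f"unknown sampling strategy {strategy!r}")
    return GeneratedSet(smiles=tuple(smiles), seed=seed, strategy=desc)
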