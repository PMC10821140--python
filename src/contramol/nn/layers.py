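"""Transformer building blocks on top of the autograd engine.

Pre-norm blocks; attention masking supports both causal (decoder) and
padding (encoder) masks. Parameters are plain :class:`Tensor` objects
registered by name so optimizers and checkpoints can address them.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

NEG_INF = -1e9


class Module:
    """Tiny nn.Module analogue: tracks parameters and submodules by name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + n: p for n, p in self._params.items()}
        for n, m in self._modules.items():
            out.update(m.named_parameters(prefix + n + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={missing} extra={extra}")
        for n, p in params.items():
            if p.data.shape != state[n].shape:
                raise ValueError(f"shape mismatch for {n}")
            p.data = np.asarray(state[n], dtype=np.float64).copy()


def _init(rng: np.random.Generator, *shape, scale: float | None = None) -> Tensor:
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _init(rng, d_in, d_out)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_rows: int, d_model: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _init(rng, n_rows, d_model, scale=0.02)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight.take_rows(ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gain + self.shift


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.data.max(axis=axis, keepdims=True)  # detached shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 causal: bool):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.causal = causal
        self.qkv = Linear(d_model, 3 * d_model, rng)
        self.out = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        B, T, D = x.shape
        H, Dh = self.n_heads, self.d_head
        qkv = self.qkv(x)  # (B, T, 3D)
        qkv = qkv.reshape(B, T, 3, H, Dh).transpose(2, 0, 3, 1, 4)  # (3,B,H,T,Dh)
        q = qkv.take_rows(np.array(0))
        k = qkv.take_rows(np.array(1))
        v = qkv.take_rows(np.array(2))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(Dh))  # (B,H,T,T)
        bias = np.zeros((B, 1, T, T))
        bias += np.where(pad_mask[:, None, None, :], 0.0, NEG_INF)  # mask keys
        if self.causal:
            bias += np.where(np.tril(np.ones((T, T), dtype=bool)), 0.0, NEG_INF)
        att = softmax(scores + Tensor(bias), axis=-1)
        ctx = att @ v  # (B,H,T,Dh)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.out(ctx)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator,
                 activation: str = "gelu"):
        super().__init__()
        self.up = Linear(d_model, d_ff, rng)
        self.down = Linear(d_ff, d_model, rng)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        h = self.up(x)
        h = h.gelu() if self.activation == "gelu" else h.relu()
        return self.down(h)


class TransformerBlock(Module):
    def __init__(self, d_model: int, d_ff: int, n_heads: int,
                 rng: np.random.Generator, causal: bool):
        super().__init__()
        self.norm1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng, causal)
        self.norm2 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray, drop=None) -> Tensor:
        a = self.attn(self.norm1(x), pad_mask)
        x = x + (drop(a) if drop else a)
        f = self.ff(self.norm2(x))
        return x + (drop(f) if drop else f)


class TransformerStack(Module):
    """Embedding + learned positions + N pre-norm blocks + final norm.

    `causal=True` gives a decoder-only stack; `causal=False` a bidirectional
    encoder. Padding positions never attend into the result, and with
    `pool="mean"` they are excluded from the pooled vector, which makes the
    output padding-invariant.
    """

    def __init__(self, vocab_size: int, d_model: int, d_ff: int, n_layers: int,
                 n_heads: int, max_len: int, rng: np.random.Generator,
                 causal: bool, dropout: float = 0.0):
        super().__init__()
        self.tok_emb = Embedding(vocab_size, d_model, rng)
        self.pos_emb = Embedding(max_len, d_model, rng)
        self.blocks = [
            TransformerBlock(d_model, d_ff, n_heads, rng, causal)
            for _ in range(n_layers)
        ]
        self.final_norm = LayerNorm(d_model)
        self.max_len = max_len
        self.dropout = dropout

    def __call__(self, ids: np.ndarray, pad_mask: np.ndarray,
                 drop_rng: np.random.Generator | None = None) -> Tensor:
        B, T = ids.shape
        if T > self.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.max_len}")
        drop = None
        if drop_rng is not None and self.dropout > 0.0:
            rate = self.dropout

            def drop(t: Tensor) -> Tensor:
                keep = drop_rng.random(t.shape) >= rate
                return t * Tensor(keep / (1.0 - rate))

        x = self.tok_emb(ids) + self.pos_emb(np.arange(T))
        for block in self.blocks:
            x = block(x, pad_mask, drop)
        return self.final_norm(x)


def mean_pool(x: Tensor, pad_mask: np.ndarray) -> Tensor:
    """Mean over non-pad positions; (B, T, D) -> (B, D)."""
    m = pad_mask.astype(np.float64)[:, :, None]
    total = (x * Tensor(m)).sum(axis=1)
    counts = m.sum(axis=1)
    return total * Tensor(1.0 / counts)


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  weight_mask: np.ndarray | None = None) -> Tensor:
    """Mean token-level cross-entropy; positions with mask 0 are excluded."""
    shifted = logits - logits.data.max(axis=-1, keepdims=True)
    logz = shifted.exp().sum(axis=-1).log()
    nll = logz - shifted.gather_last(targets)
    if weight_mask is None:
        return nll.mean()
    w = weight_mask.astype(np.float64)
    return (nll * Tensor(w)).sum() * (1.0 / w.sum())
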