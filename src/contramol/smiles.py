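"""SMILES validation, canonicalization, randomized enumeration, tokenization.

Canonical-form string equality is the molecule-identity predicate used
throughout the package (uniqueness, novelty, round-trip checks).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
SPECIALS = (PAD, BOS, EOS, UNK)

DEFAULT_MAX_LEN = 100

# Bracket atoms, %nn ring closures and two-letter elements are single tokens;
# everything else is one character.
_TOKEN_RE = re.compile(r"\[[^\]]*\]|%\d{2}|Cl|Br|.")


class InvalidSmilesError(ValueError):
    """Raised when an operation requiring a valid SMILES receives an invalid one."""


def _mol_from_smiles(s: str):
    if not isinstance(s, str) or not s:
        return None
    return Chem.MolFromSmiles(s)


def validate_smiles(s: str) -> bool:
    """True iff the structure parser accepts ``s``. Never raises."""
    try:
        return _mol_from_smiles(s) is not None
    except Exception:  # noqa: BLE001 - contract: malformed input returns False
        return False


def canonicalize(s: str) -> str:
    mol = _mol_from_smiles(s)
    if mol is None:
        raise InvalidSmilesError(f"not a valid SMILES: {s!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class MoleculeRecord:
    raw: str
    canonical: str | None
    is_valid: bool

    @classmethod
    def from_smiles(cls, s: str) -> "MoleculeRecord":
        mol = _mol_from_smiles(s)
        if mol is None:
            return cls(raw=s, canonical=None, is_valid=False)
        return cls(raw=s, canonical=Chem.MolToSmiles(mol), is_valid=True)


@dataclass(frozen=True)
class ViewPair:
    x1: str
    x2: str
    source_canonical: str


def enumerate_smiles(s: str, n: int, seed: int) -> list[str]:
    """`n` randomized writings of `s`: the atom order is shuffled before the
    (non-canonical) DFS writer runs, so the traversal start and order vary."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mol = _mol_from_smiles(s)
    if mol is None:
        raise InvalidSmilesError(f"not a valid SMILES: {s!r}")
    rng = np.random.default_rng(seed)
    n_atoms = mol.GetNumAtoms()
    out = []
    for _ in range(n):
        perm = rng.permutation(n_atoms).tolist()
        shuffled = Chem.RenumberAtoms(mol, perm)
        out.append(Chem.MolToSmiles(shuffled, canonical=False))
    return out


def sample_view_pair(s: str, seed: int) -> ViewPair:
    """Two independently enumerated writings of one molecule (may coincide
    for small molecules; kept as-is)."""
    x1, x2 = enumerate_smiles(s, 2, seed)
    return ViewPair(x1=x1, x2=x2, source_canonical=canonicalize(s))


def tokenize_string(s: str) -> list[str]:
    return _TOKEN_RE.findall(s)


@dataclass(frozen=True)
class TokenVocabulary:
    """Dense token<->id map with pad/bos/eos/unk reserved at ids 0..3."""

    tokens: tuple[str, ...]

    def __post_init__(self):
        if tuple(self.tokens[:4]) != SPECIALS:
            raise ValueError("vocabulary must start with the four special tokens")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        object.__setattr__(
            self, "_ids", {t: i for i, t in enumerate(self.tokens)}
        )

    @property
    def size(self) -> int:
        return len(self.tokens)

    pad_id, bos_id, eos_id, unk_id = 0, 1, 2, 3

    def id_of(self, token: str) -> int:
        return self._ids.get(token, self.unk_id)

    def token_of(self, idx: int) -> str:
        if not 0 <= idx < len(self.tokens):
            raise IndexError(f"token id {idx} out of range")
        return self.tokens[idx]

    @classmethod
    def build(cls, corpus: list[str]) -> "TokenVocabulary":
        if not corpus:
            raise ValueError("cannot build a vocabulary from an empty corpus")
        seen: dict[str, None] = {}
        for s in corpus:
            for tok in tokenize_string(s):
                seen.setdefault(tok, None)
        return cls(tokens=SPECIALS + tuple(seen))

    def save(self, path: str | Path):
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TokenVocabulary":
        return cls(tokens=tuple(Path(path).read_text().splitlines()))


@dataclass(frozen=True)
class TokenizedSequence:
    ids: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.ids)


def tokenize(s: str, vocab: TokenVocabulary,
             max_len: int = DEFAULT_MAX_LEN) -> TokenizedSequence:
    body = [vocab.id_of(t) for t in tokenize_string(s)]
    ids = (vocab.bos_id, *body, vocab.eos_id)
    if len(ids) > max_len:
        raise ValueError(
            f"tokenized length {len(ids)} exceeds max length {max_len}"
        )
    return TokenizedSequence(ids=ids)


def detokenize(t: TokenizedSequence | tuple[int, ...] | list[int],
               vocab: TokenVocabulary) -> str:
    ids = t.ids if isinstance(t, TokenizedSequence) else tuple(t)
    parts = []
    for idx in ids:
        tok = vocab.token_of(int(idx))
        if tok == EOS:
            break
        if tok in (PAD, BOS, UNK):
            continue
        parts.append(tok)
    return "".join(parts)


def pad_batch(seqs: list[TokenizedSequence], pad_id: int = 0,
              length: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad to a rectangle; returns (ids, mask) with mask True on real tokens."""
    T = length if length is not None else max(s.length for s in seqs)
    ids = np.full((len(seqs), T), pad_id, dtype=np.int64)
    mask = np.zeros((len(seqs), T), dtype=bool)
    for i, s in enumerate(seqs):
        ids[i, : s.length] = s.ids
        mask[i, : s.length] = True
    return ids, mask


# -- corpus I/O ----------------------------------------------------------------

def read_smi(path: str | Path) -> list[str]:
    """One SMILES per line; an optional whitespace-separated name is ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        out.append(line.split()[0])
    return out


def write_smi(smiles: list[str], path: str | Path):
    Path(path).write_text("".join(s + "\n" for s in smiles))


def read_csv_smiles(path: str | Path, column: str = "smiles") -> list[str]:
    """SMILES column from a CSV; internal whitespace is stripped (printed
    tables sometimes wrap SMILES across lines)."""
    df = pd.read_csv(path)
    if column not in df.columns:
        raise ValueError(f"column {column!r} not found in {path}")
    return [re.sub(r"\s+", "", str(s)) for s in df[column]]


def load_corpus(path: str | Path, column: str = "smiles") -> list[MoleculeRecord]:
    path = Path(path)
    raw = read_csv_smiles(path, column) if path.suffix == ".csv" else read_smi(path)
    return [MoleculeRecord.from_smiles(s) for s in raw]
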