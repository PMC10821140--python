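"""Synthetic corpora, dataset filters and seeded splits.

The toy SMILES generator assembles drug-like molecules from aromatic /
saturated ring cores plus substituent decorations (amides, ureas, ethers),
tuned so that a useful share lands inside the lead-like filter window.
The toy CPI table plants a learnable conjunction signal: label 1 iff the
molecule carries a fluorine marker AND the protein carries a k-mer motif.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .smiles import MoleculeRecord, validate_smiles


@dataclass(frozen=True)
class FilterSpec:
    mw_min: float = 250.0
    mw_max: float = 350.0
    logp_max: float = 3.5
    max_smiles_len: int = 100

    def __post_init__(self):
        if self.mw_min >= self.mw_max:
            raise ValueError("mw_min must be below mw_max")


def filter_pretraining_candidates(corpus: list[MoleculeRecord],
                                  spec: FilterSpec = FilterSpec()) -> list[MoleculeRecord]:
    """Keep records with mw_min <= MW <= mw_max, LogP <= logp_max and
    canonical length <= max_smiles_len. Order-preserving."""
    kept = []
    for rec in corpus:
        if not rec.is_valid:
            continue
        if len(rec.canonical) > spec.max_smiles_len:
            continue
        mol = Chem.MolFromSmiles(rec.canonical)
        if not spec.mw_min <= Descriptors.MolWt(mol) <= spec.mw_max:
            continue
        if Crippen.MolLogP(mol) > spec.logp_max:
            continue
        kept.append(rec)
    return kept


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, ...]
    seed: int = 0

    def __post_init__(self):
        if not self.ratios or any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be positive")


def split_dataset(records: list, spec: SplitSpec) -> list[list]:
    """Seeded shuffle, then contiguous partition at the ratio boundaries.
    Partitions are disjoint and exhaustive."""
    n = len(records)
    if n < len(spec.ratios):
        raise ValueError("more splits than records")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    fractions = np.cumsum(spec.ratios) / sum(spec.ratios)
    boundaries = [0] + [int(round(f * n)) for f in fractions]
    boundaries[-1] = n
    return [
        [records[i] for i in order[lo:hi]]
        for lo, hi in zip(boundaries[:-1], boundaries[1:])
    ]


# -- toy SMILES corpus ---------------------------------------------------------

# Ring cores with two decoration sites; digit 1 is reserved for the core ring.
_CORES = (
    "{a}c1ccc({b})cc1",
    "{a}c1cccc({b})c1",
    "{a}c1ccc({b})nc1",
    "{a}c1cc({b})no1",
    "{a}C1CCN({b})CC1",
)

# Prefix substituents bond to the first ring atom through their last atom.
_LEFT = ("C", "CC", "CO", "COC", "CCO", "N#C", "CC(C)", "CN(C)",
         "CC(=O)N", "FC(F)(F)", "CS(=O)(=O)", "CCOC", "CCOC(=O)",
         "CC(C)(C)", "COCCO")

# Branch substituents; digits 2/3 keep substituent rings clear of the core.
# Heavier decorations are drawn more often so the corpus leans into the
# 250-350 Da lead-like window.
_RIGHT_LIGHT = ("C", "OC", "N(C)C", "C#N", "F", "Cl", "OCC", "CC")
_RIGHT_HEAVY = (
    "C(=O)N2CCCCC2", "C(=O)N2CCCC2", "C(=O)N2CCOCC2",
    "NC(=O)C2CCCCC2", "NC(=O)N2CCCC2", "N2CCN(C(C)=O)CC2",
    "C(=O)N2CCN(C(=O)C3CCCCC3)CC2", "NC(=O)N2CCN(C(=O)C3CCCC3)CC2",
    "S(=O)(=O)N2CCCC2", "C(=O)NCc2ccccc2", "NC(=O)c2ccccc2",
    "OCc2ccccc2", "C(=O)NC2CCCCC2", "N2CCC(C(N)=O)CC2",
)
_HEAVY_PROB = 0.72

# Appended to the ring-closure atom of the core.
_TAIL = ("", "C", "F", "Cl", "O", "OC", "N")


def _assemble(core: str, a: str, b: str, tail: str) -> str:
    return core.format(a=a, b=b) + tail


def make_toy_smiles_corpus(n: int, seed: int) -> list[MoleculeRecord]:
    """`n` distinct valid drug-like molecules; distinctness by canonical form."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    attempts, max_attempts = 0, 300 * n + 1000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"combinatorial space exhausted after {attempts} attempts "
                f"({len(out)}/{n} molecules)"
            )
        right_pool = _RIGHT_HEAVY if rng.random() < _HEAVY_PROB else _RIGHT_LIGHT
        s = _assemble(
            _CORES[rng.integers(len(_CORES))],
            _LEFT[rng.integers(len(_LEFT))],
            right_pool[rng.integers(len(right_pool))],
            _TAIL[rng.integers(len(_TAIL))],
        )
        if not validate_smiles(s):
            continue
        rec = MoleculeRecord.from_smiles(s)
        if rec.canonical in seen:
            continue
        seen.add(rec.canonical)
        out.append(rec)
    return out


# -- toy CPI dataset -----------------------------------------------------------

PROTEIN_MOTIF = "WYWKY"
MOLECULE_MARKER = "F"  # fluorine atom; C/N/O/F/S/Cl chemistry keeps this unambiguous


def molecule_has_marker(canonical: str) -> bool:
    return MOLECULE_MARKER in canonical


def protein_has_motif(seq: str) -> bool:
    return PROTEIN_MOTIF in seq


def rule_based_cpi_detector(smiles_canonical: str, protein: str) -> int:
    """Oracle for the planted signal; F1 = 1 on noise-free data by construction."""
    return int(molecule_has_marker(smiles_canonical) and protein_has_motif(protein))


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng: np.random.Generator, with_motif: bool,
                    length_range=(30, 45)) -> str:
    while True:
        length = int(rng.integers(*length_range))
        seq = "".join(_AA[i] for i in rng.integers(len(_AA), size=length))
        if protein_has_motif(seq):
            continue  # never by accident
        if with_motif:
            pos = int(rng.integers(0, length - len(PROTEIN_MOTIF) + 1))
            seq = seq[:pos] + PROTEIN_MOTIF + seq[pos + len(PROTEIN_MOTIF):]
        return seq


def _marker_partitioned_molecules(seed: int, pool_size: int = 600
                                  ) -> tuple[list[str], list[str]]:
    """Molecule pools with / without the marker; records sample from these
    with replacement (one molecule may pair with many proteins)."""
    corpus = make_toy_smiles_corpus(pool_size, seed)
    with_m = [r.canonical for r in corpus if molecule_has_marker(r.canonical)]
    without = [r.canonical for r in corpus if not molecule_has_marker(r.canonical)]
    if len(with_m) < 20 or len(without) < 20:
        raise RuntimeError("toy chemistry cannot supply enough marker molecules")
    return with_m, without


def make_toy_cpi_dataset(n: int, seed: int, noise: float = 0.0) -> list:
    """Balanced planted-signal CPI table. Positives pair a marker molecule
    with a motif protein; negatives break one or both conjuncts. `noise`
    flips each label independently."""
    from .cpi import CPIRecord  # local import to avoid a cycle

    if n < 2:
        raise ValueError("need n >= 2 for a balanced dataset")
    if not 0.0 <= noise < 1.0:
        raise ValueError("noise must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    n_neg = n - n_pos
    # negatives: split across (marker only, motif only, neither)
    n_marker_only = n_neg // 3
    n_motif_only = n_neg // 3
    n_neither = n_neg - n_marker_only - n_motif_only

    with_m, without_m = _marker_partitioned_molecules(seed + 7)
    records = []
    groups = (
        (n_pos, True, True),
        (n_marker_only, True, False),
        (n_motif_only, False, True),
        (n_neither, False, False),
    )
    for count, marker, motif in groups:
        for _ in range(count):
            pool = with_m if marker else without_m
            smiles = pool[rng.integers(len(pool))]
            protein = _random_protein(rng, with_motif=motif)
            label = int(marker and motif)
            if noise > 0 and rng.random() < noise:
                label = 1 - label
            records.append(CPIRecord(smiles=smiles, protein=protein, label=label))
    order = rng.permutation(len(records))
    return [records[i] for i in order]
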