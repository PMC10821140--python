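"""Evaluation layer: distribution-learning metrics for generated molecule
sets, molecular property profiling, pairwise fingerprint similarity, and
binary-classification metrics.
"""

from __future__ import annotations

import json
import os
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import QED, Crippen, Descriptors, RDConfig, rdFingerprintGenerator
from rdkit.Chem import rdMolDescriptors

from .smiles import InvalidSmilesError, canonicalize, validate_smiles

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, resolved via RDConfig)

DEFAULT_FINGERPRINT = "morgan-2-2048"


# -- fingerprints --------------------------------------------------------------

def _fingerprint(mol, spec: str):
    """Binary fingerprint per spec string: 'morgan-<radius>-<nbits>',
    'rdkit' (path-based, 2048 bits) or 'maccs'."""
    if spec.startswith("morgan-"):
        _, radius, nbits = spec.split("-")
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=int(radius), fpSize=int(nbits)
        )
        return gen.GetFingerprint(mol)
    if spec == "rdkit":
        return Chem.RDKFingerprint(mol)
    if spec == "maccs":
        from rdkit.Chem import MACCSkeys

        return MACCSkeys.GenMACCSKeys(mol)
    raise ValueError(f"unknown fingerprint spec {spec!r}")


def tanimoto(s1: str, s2: str, fp: str = DEFAULT_FINGERPRINT) -> float:
    """Bit-set Jaccard similarity between the two molecules' fingerprints."""
    mols = []
    for s in (s1, s2):
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise InvalidSmilesError(f"not a valid SMILES: {s!r}")
        mols.append(mol)
    return DataStructs.TanimotoSimilarity(
        _fingerprint(mols[0], fp), _fingerprint(mols[1], fp)
    )


# -- generation metrics --------------------------------------------------------

def validity(generated: list[str]) -> float:
    if not generated:
        raise ValueError("empty generated list")
    return sum(validate_smiles(s) for s in generated) / len(generated)


def unique_at_k(generated: list[str], k: int = 10_000) -> float:
    """Distinct canonical forms among the first min(k, #valid) valid strings,
    in generation order. With fewer than k valid molecules the denominator
    falls back to the number of valid molecules."""
    if k < 1:
        raise ValueError("k must be >= 1")
    taken = []
    for s in generated:
        if len(taken) == k:
            break
        if validate_smiles(s):
            taken.append(canonicalize(s))
    if not taken:
        raise ValueError("no valid molecules in the generated list")
    return len(set(taken)) / len(taken)


def novelty(generated_unique: set[str], training: set[str]) -> float:
    if not generated_unique:
        raise ValueError("empty generated set")
    return len(generated_unique - training) / len(generated_unique)


def success_rate(v: float, u: float, n: float) -> float:
    for name, x in (("validity", v), ("uniqueness", u), ("novelty", n)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} out of [0, 1]: {x}")
    return v * u * n


def internal_diversity(smiles: list[str], p: int = 1,
                       fp: str = DEFAULT_FINGERPRINT) -> float:
    """1 - (mean of T(s1,s2)^p over ALL ordered pairs, self-pairs included)^(1/p)."""
    if not smiles:
        raise ValueError("empty molecule set")
    if p < 1:
        raise ValueError("p must be >= 1")
    mols = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise InvalidSmilesError(f"not a valid SMILES: {s!r}")
        mols.append(_fingerprint(mol, fp))
    m = len(mols)
    sims = np.empty((m, m))
    for i, f in enumerate(mols):
        sims[i] = DataStructs.BulkTanimotoSimilarity(f, mols)
    return 1.0 - float((sims ** p).mean()) ** (1.0 / p)


@dataclass(frozen=True)
class GenerationMetrics:
    validity: float
    unique_at_k: float
    novelty: float
    success_rate: float
    intdiv: float
    k: int
    p: int

    def rounded(self, ndigits: int = 3) -> dict:
        return {k: round(v, ndigits) if isinstance(v, float) else v
                for k, v in asdict(self).items()}


def evaluate_generation(generated: list[str], training_canonical: set[str],
                        k: int = 10_000, p: int = 1,
                        fp: str = DEFAULT_FINGERPRINT) -> GenerationMetrics:
    """All five generation metrics for a raw generated set."""
    v = validity(generated)
    u = unique_at_k(generated, k)
    valid_canon = [canonicalize(s) for s in generated if validate_smiles(s)]
    uniq = set(valid_canon)
    nov = novelty(uniq, training_canonical)
    idiv = internal_diversity(sorted(uniq), p=p, fp=fp)
    return GenerationMetrics(
        validity=v, unique_at_k=u, novelty=nov,
        success_rate=success_rate(v, u, nov), intdiv=idiv, k=k, p=p,
    )


# -- property profiling --------------------------------------------------------

def property_profile(smiles: list[str]) -> pd.DataFrame:
    """QED (Bickerton), Crippen LogP, Ertl-Schuffenhauer SAScore, Ertl TPSA
    and molecular weight, one row per molecule."""
    rows = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise InvalidSmilesError(f"not a valid SMILES: {s!r}")
        rows.append({
            "smiles": s,
            "qed": QED.qed(mol),
            "logp": Crippen.MolLogP(mol),
            "sascore": sascorer.calculateScore(mol),
            "tpsa": rdMolDescriptors.CalcTPSA(mol),
            "mw": Descriptors.MolWt(mol),
        })
    return pd.DataFrame(rows)


PROFILE_PROPERTIES = ("qed", "logp", "sascore", "tpsa", "mw")


def compare_property_distributions(gen: pd.DataFrame, ref: pd.DataFrame,
                                   bins: int = 30) -> dict:
    """Aligned per-property histograms (shared bins) and mean/sd summaries."""
    if gen.empty or ref.empty:
        raise ValueError("property profiles must be non-empty")
    out = {}
    for prop in PROFILE_PROPERTIES:
        g, r = gen[prop].to_numpy(float), ref[prop].to_numpy(float)
        lo = min(g.min(), r.min())
        hi = max(g.max(), r.max())
        if hi == lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, bins + 1)
        out[prop] = {
            "bin_edges": edges.tolist(),
            "gen_hist": np.histogram(g, bins=edges)[0].tolist(),
            "ref_hist": np.histogram(r, bins=edges)[0].tolist(),
            "gen_mean": float(g.mean()), "gen_sd": float(g.std(ddof=0)),
            "ref_mean": float(r.mean()), "ref_sd": float(r.std(ddof=0)),
            "mean_difference": float(g.mean() - r.mean()),
        }
    return out


def plot_property_distributions(comparison: dict, path: str | Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    props = list(comparison)
    fig, axes = plt.subplots(1, len(props), figsize=(4 * len(props), 3))
    for ax, prop in zip(np.atleast_1d(axes), props):
        d = comparison[prop]
        centers = (np.array(d["bin_edges"][:-1]) + np.array(d["bin_edges"][1:])) / 2
        ax.plot(centers, d["ref_hist"], label="reference")
        ax.plot(centers, d["gen_hist"], label="generated")
        ax.set_title(prop)
    axes_flat = np.atleast_1d(axes)
    axes_flat[0].legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# -- classification metrics ----------------------------------------------------

@dataclass(frozen=True)
class ClassificationMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool  # True when a zero denominator forced a 0 report


def classification_metrics(tp: int, fp: int, fn: int, tn: int) -> ClassificationMetrics:
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn + tn == 0:
        raise ValueError("all counts are zero")
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassificationMetrics(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                                 recall=recall, f1=f1, degenerate=degenerate)


def write_generation_report(metrics: GenerationMetrics, path: str | Path,
                            settings: dict | None = None):
    report = {
        "metrics": asdict(metrics),
        "metrics_rounded": metrics.rounded(),
        "settings": settings or {},
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
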