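import itertools

import numpy as np
import pytest
from rdkit import Chem, DataStructs

from contramol import metrics
from contramol.smiles import InvalidSmilesError, canonicalize

# Printed case-study rows: (generated SMILES, test-set SMILES) after
# whitespace stripping, plus the published component metrics used for the
# success-rate product identity.
CASE_STUDY_PAIRS = [
    ("COc1ccc(NC(=O)N2CCN(C(=O)C3CCCCC3)CC2)cc1",
     "COc1ccc(NC(=O)N2CCN(C(=O)C3CCCC3)CC2)cc1"),
    ("Cc1nc2cc3c(cc2n1CC(=O)NC1CCCCC1)OCCO3",
     "Cc1nc2cc3c(cc2n1CC(=O)NC1CCCC1)OCCO3"),
    ("Cn1ccc(C(=O)Nc2cc(F)ccc2N2CCCC2)cc1=O",
     "Cn1ccc(C(=O)Nc2cc(F)ccc2N2CCCCC2)cc1=O"),
    ("Cc1cc(CN(C)C(=O)Nc2ccccc2N2CCCC2)no1",
     "Cc1cc(CN(C)C(=O)Nc2ccccc2N2CCCCC2)no1"),
    ("COc1ccccc1-c1noc(C(=O)N2CCCC2)c1N",
     "COc1ccccc1-c1noc(C(=O)N2CCCCC2)c1N"),
    ("CC(CC#N)N(C)C(=O)Nc1ccccc1N1CCCC1",
     "CC(CC#N)N(C)C(=O)Nc1ccccc1N1CCCCC1"),
]

# (validity, uniqueness, novelty, printed success rate) for every published
# benchmark row; the product identity must hold at 3-dp rounding.
BENCHMARK_ROWS = [
    ("moses/CharRNN", 0.975, 0.999, 0.842, 0.820),
    ("moses/VAE", 0.977, 0.998, 0.695, 0.678),
    ("moses/AAE", 0.937, 0.997, 0.793, 0.741),
    ("moses/LatentGAN", 0.897, 0.997, 0.949, 0.849),
    ("moses/JT-VAE", 1.0, 0.999, 0.914, 0.913),
    ("moses/MolGPT", 0.995, 1.0, 0.781, 0.777),
    ("moses/unfrozen", 0.992, 1.0, 0.791, 0.785),
    ("moses/frozen", 0.991, 1.0, 0.834, 0.826),
    ("guacamol/SMILES-LSTM", 0.959, 1.0, 0.912, 0.875),
    ("guacamol/VAE", 0.870, 0.999, 0.974, 0.847),
    ("guacamol/AAE", 0.822, 1.0, 0.998, 0.820),
    ("guacamol/MolGPT", 0.979, 0.998, 0.958, 0.936),
    ("guacamol/unfrozen", 0.968, 0.999, 0.968, 0.936),
    ("guacamol/frozen", 0.961, 0.999, 0.975, 0.936),
]


class TestValidity:
    def test_two_of_three(self):
        assert metrics.validity(["CCO", "c1ccccc1", "C1CC"]) == pytest.approx(2 / 3)

    def test_all_valid(self):
        assert metrics.validity(["CCO", "CC"]) == 1.0

    def test_all_invalid(self):
        assert metrics.validity(["xx", "C1CC"]) == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            metrics.validity([])


class TestUniqueAtK:
    def test_rewriting_collapses(self):
        gen = ["CCO", "OCC", "CC", "CCC", "CCCC"]
        assert metrics.unique_at_k(gen, 5) == pytest.approx(4 / 5)

    def test_all_identical(self):
        assert metrics.unique_at_k(["CCO"] * 7, 10) == pytest.approx(1 / 7)

    def test_fewer_valid_than_k_uses_valid_count(self):
        gen = ["CCO", "bad", "CC"]
        assert metrics.unique_at_k(gen, 10) == 1.0

    def test_k_window_applies_to_valid_strings_only(self):
        gen = ["bad", "CCO", "CC", "CCC"]
        assert metrics.unique_at_k(gen, 2) == 1.0  # first 2 valid: CCO, CC

    def test_no_valid_raises(self):
        with pytest.raises(ValueError):
            metrics.unique_at_k(["bad"], 5)


class TestNovelty:
    def test_two_thirds(self):
        assert metrics.novelty({"A", "B", "C"}, {"A"}) == pytest.approx(2 / 3)

    def test_disjoint(self):
        assert metrics.novelty({"A"}, {"B"}) == 1.0

    def test_subset(self):
        assert metrics.novelty({"A"}, {"A", "B"}) == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            metrics.novelty(set(), {"A"})


class TestSuccessRate:
    def test_perfect(self):
        assert metrics.success_rate(1, 1, 1) == 1.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            metrics.success_rate(1.2, 1, 1)

    @pytest.mark.parametrize("row,v,u,n,printed", BENCHMARK_ROWS)
    def test_product_identity_all_published_rows(self, row, v, u, n, printed):
        assert round(metrics.success_rate(v, u, n), 3) == printed


class TestTanimoto:
    def test_self_similarity(self):
        assert metrics.tanimoto("CCO", "CCO") == 1.0

    def test_symmetry(self):
        a, b = CASE_STUDY_PAIRS[0]
        assert metrics.tanimoto(a, b) == metrics.tanimoto(b, a)

    def test_invalid_raises(self):
        with pytest.raises(InvalidSmilesError):
            metrics.tanimoto("bad", "CCO")

    def test_matches_rdkit_direct(self):
        a, b = CASE_STUDY_PAIRS[1]
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        fa = gen.GetFingerprint(Chem.MolFromSmiles(a))
        fb = gen.GetFingerprint(Chem.MolFromSmiles(b))
        assert metrics.tanimoto(a, b) == pytest.approx(
            DataStructs.TanimotoSimilarity(fa, fb)
        )


class TestInternalDiversity:
    def test_repeated_molecule_is_zero(self):
        assert metrics.internal_diversity(["CCO"] * 5) == pytest.approx(0.0)

    def test_singleton_is_zero(self):
        assert metrics.internal_diversity(["CCO"]) == pytest.approx(0.0)

    @pytest.mark.parametrize("p", [1, 2])
    def test_matches_double_loop_oracle(self, p, toy_corpus_100):
        mols = [r.canonical for r in toy_corpus_100[:10]]
        got = metrics.internal_diversity(mols, p=p)
        # independent double loop over all ordered pairs incl. self-pairs
        total = 0.0
        for s1, s2 in itertools.product(mols, mols):
            total += metrics.tanimoto(s1, s2) ** p
        expected = 1.0 - (total / len(mols) ** 2) ** (1.0 / p)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_reorder_invariant(self, toy_corpus_100):
        mols = [r.canonical for r in toy_corpus_100[:8]]
        assert metrics.internal_diversity(mols) == pytest.approx(
            metrics.internal_diversity(mols[::-1]), abs=1e-12
        )


class TestPropertyProfile:
    def test_methane(self):
        row = metrics.property_profile(["C"]).iloc[0]
        assert row.mw == pytest.approx(16.04, abs=0.01)
        assert row.tpsa == 0.0

    def test_ranges(self, toy_corpus_100):
        df = metrics.property_profile([r.canonical for r in toy_corpus_100[:20]])
        assert ((df.qed >= 0) & (df.qed <= 1)).all()
        assert ((df.sascore >= 1) & (df.sascore <= 10)).all()
        assert (df.tpsa >= 0).all()
        assert (df.mw > 0).all()

    def test_invalid_raises(self):
        with pytest.raises(InvalidSmilesError):
            metrics.property_profile(["bad"])


class TestEvaluateGeneration:
    def test_product_identity_holds_exactly(self, toy_corpus_100):
        gen = [r.canonical for r in toy_corpus_100[:30]] + ["C1CC"]
        training = {r.canonical for r in toy_corpus_100[:10]}
        m = metrics.evaluate_generation(gen, training, k=25)
        assert m.success_rate == pytest.approx(
            m.validity * m.unique_at_k * m.novelty, abs=1e-12
        )
        for value in (m.validity, m.unique_at_k, m.novelty, m.success_rate,
                      m.intdiv):
            assert 0.0 <= value <= 1.0


class TestClassificationMetrics:
    def test_perfect(self):
        m = metrics.classification_metrics(tp=1, fp=0, fn=0, tn=0)
        assert m.precision == m.recall == m.f1 == 1.0
        assert not m.degenerate

    def test_half_precision(self):
        m = metrics.classification_metrics(tp=50, fp=50, fn=0, tn=0)
        assert m.precision == 0.5
        assert m.recall == 1.0
        assert m.f1 == pytest.approx(2 / 3)

    def test_no_positive_predictions(self):
        m = metrics.classification_metrics(tp=0, fp=0, fn=5, tn=5)
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0
        assert m.degenerate

    def test_f1_harmonic_identity(self):
        m = metrics.classification_metrics(tp=30, fp=10, fn=20, tn=40)
        assert m.f1 == pytest.approx(
            2 * m.precision * m.recall / (m.precision + m.recall)
        )

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            metrics.classification_metrics(0, 0, 0, 0)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            metrics.classification_metrics(-1, 0, 0, 1)


class TestComparePropertyDistributions:
    def test_identical_profiles(self, toy_corpus_100):
        df = metrics.property_profile([r.canonical for r in toy_corpus_100[:15]])
        cmp = metrics.compare_property_distributions(df, df)
        for prop, d in cmp.items():
            assert d["gen_hist"] == d["ref_hist"]
            assert d["mean_difference"] == 0.0

    def test_shifted_logp(self, toy_corpus_100):
        df = metrics.property_profile([r.canonical for r in toy_corpus_100[:15]])
        shifted = df.copy()
        shifted["logp"] = shifted["logp"] + 1.0
        cmp = metrics.compare_property_distributions(shifted, df)
        assert cmp["logp"]["mean_difference"] == pytest.approx(1.0)

    def test_json_serializable(self, toy_corpus_100, tmp_path):
        import json

        df = metrics.property_profile([r.canonical for r in toy_corpus_100[:10]])
        cmp = metrics.compare_property_distributions(df, df)
        (tmp_path / "c.json").write_text(json.dumps(cmp))

    def test_plot_smoke(self, toy_corpus_100, tmp_path):
        df = metrics.property_profile([r.canonical for r in toy_corpus_100[:10]])
        cmp = metrics.compare_property_distributions(df, df)
        out = tmp_path / "dist.png"
        metrics.plot_property_distributions(cmp, out)
        assert out.stat().st_size > 0

    def test_empty_raises(self, toy_corpus_100):
        import pandas as pd

        df = metrics.property_profile([r.canonical for r in toy_corpus_100[:5]])
        with pytest.raises(ValueError):
            metrics.compare_property_distributions(df, pd.DataFrame())
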