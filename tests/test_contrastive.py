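import numpy as np
import pytest

from contramol import contrastive
from contramol.contrastive import (
    ContrastiveConfig,
    ContrastiveModel,
    cosine_similarity,
    extract_embedding,
    nt_xent_loss,
    pretrain,
)
from contramol.nn import CheckpointError, Tensor
from contramol.smiles import TokenVocabulary, pad_batch, tokenize


def naive_nt_xent(z: np.ndarray, tau: float) -> float:
    """Independent double-loop oracle."""
    n = len(z)
    norm = z / np.linalg.norm(z, axis=1, keepdims=True)
    total = 0.0
    for i in range(n):
        j = i ^ 1
        num = np.exp(norm[i] @ norm[j] / tau)
        den = 0.0
        for k in range(n):
            if k != i:
                den += np.exp(norm[i] @ norm[k] / tau)
        total += -np.log(num / den)
    return total / n


class TestCosineSimilarity:
    def test_identical(self):
        assert cosine_similarity([1, 0], [1, 0]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_opposite(self):
        assert cosine_similarity([1, 1], [-1, -1]) == pytest.approx(-1.0)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])


class TestNTXent:
    def test_single_molecule_loss_is_zero(self, rng):
        z = rng.normal(size=(2, 4))
        assert float(nt_xent_loss(z, 0.5).data) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_n2(self):
        z = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        expected = -np.log(np.e / (np.e + 2))
        assert float(nt_xent_loss(z, 1.0).data) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.5514, abs=5e-5)

    def test_matches_oracle_on_random_batches(self, rng):
        for _ in range(100):
            N = int(rng.integers(1, 5))
            d = int(rng.integers(2, 9))
            tau = float(rng.uniform(0.05, 2.0))
            z = rng.normal(size=(2 * N, d))
            got = float(nt_xent_loss(z, tau).data)
            assert got == pytest.approx(naive_nt_xent(z, tau), abs=1e-6)

    def test_permutation_invariance_over_molecules(self, rng):
        z = rng.normal(size=(8, 5))
        base = float(nt_xent_loss(z, 0.2).data)
        perm = np.array([2, 3, 6, 7, 0, 1, 4, 5])  # permute molecules, keep pairs
        assert float(nt_xent_loss(z[perm], 0.2).data) == pytest.approx(
            base, abs=1e-6
        )

    def test_loss_decreases_with_positive_similarity(self):
        z = np.array([[1.0, 0.2], [0.5, 0.8], [-1.0, 0.3], [0.2, -0.9]])
        better = z.copy()
        better[1] = z[0]  # make the positive pair identical
        assert float(nt_xent_loss(better, 0.5).data) < float(
            nt_xent_loss(z, 0.5).data
        )

    def test_gradient_direction_via_finite_difference(self, rng):
        # increasing only the positive-pair similarity lowers the loss
        z = rng.normal(size=(6, 4))
        t = Tensor(z, requires_grad=True)
        nt_xent_loss(t, 0.5).backward()
        step = z.copy()
        step[1] += 1e-4 * (z[0] - z[1])  # nudge view 1 toward its partner
        assert float(nt_xent_loss(step, 0.5).data) < float(
            nt_xent_loss(z, 0.5).data
        )

    def test_bad_temperature(self, rng):
        with pytest.raises(ValueError):
            nt_xent_loss(rng.normal(size=(4, 3)), 0.0)

    def test_odd_batch_raises(self, rng):
        with pytest.raises(ValueError):
            nt_xent_loss(rng.normal(size=(3, 3)), 0.5)


class TestConfig:
    def test_defaults_match_published_training_setup(self):
        cfg = ContrastiveConfig()
        assert cfg.embed_dim == 256
        assert cfg.batch_molecules == 16
        assert cfg.temperature == 0.1
        assert cfg.max_epochs == 100
        assert cfg.patience == 10

    @pytest.mark.parametrize("field,value", [
        ("temperature", 0.0), ("temperature", -1.0),
        ("embed_dim", 0), ("learning_rate", 0.0),
    ])
    def test_invalid_rejected(self, field, value):
        cfg = ContrastiveConfig(**{field: value})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_patience_exceeding_epochs_rejected(self):
        with pytest.raises(ValueError):
            ContrastiveConfig(max_epochs=5, patience=10).validate()


@pytest.fixture(scope="module")
def small_model_setup():
    corpus = ["CCO", "CCN", "CCCl", "c1ccccc1", "CC(=O)O", "CCOC"]
    vocab = TokenVocabulary.build(corpus)
    cfg = ContrastiveConfig(
        embed_dim=16, encoder_layers=1, attention_heads=2, ff_dim=32,
        proj_hidden_dim=16, proj_out_dim=8, batch_molecules=4,
        max_epochs=2, patience=2, max_len=40,
    )
    model = ContrastiveModel(vocab.size, cfg, np.random.default_rng(0))
    return corpus, vocab, cfg, model


class TestEncodeViews:
    def test_identical_views_identical_vectors(self, small_model_setup):
        corpus, vocab, cfg, model = small_model_setup
        seqs = [tokenize("CCO", vocab), tokenize("CCO", vocab)]
        ids, mask = pad_batch(seqs)
        r = model.encode_views(ids, mask).data
        np.testing.assert_allclose(r[0], r[1])

    def test_padding_invariance(self, small_model_setup):
        corpus, vocab, cfg, model = small_model_setup
        seqs = [tokenize("CCO", vocab)]
        ids, mask = pad_batch(seqs)
        ids_padded, mask_padded = pad_batch(seqs, length=ids.shape[1] + 7)
        r1 = model.encode_views(ids, mask).data
        r2 = model.encode_views(ids_padded, mask_padded).data
        np.testing.assert_allclose(r1, r2, atol=1e-10)

    def test_permutation_equivariance(self, small_model_setup):
        corpus, vocab, cfg, model = small_model_setup
        seqs = [tokenize(s, vocab) for s in corpus[:4]]
        ids, mask = pad_batch(seqs)
        base = model.encode_views(ids, mask).data
        perm = np.array([2, 0, 3, 1])
        permuted = model.encode_views(ids[perm], mask[perm]).data
        np.testing.assert_allclose(permuted, base[perm], atol=1e-10)


class TestProject:
    def test_matches_matrix_oracle(self, small_model_setup, rng):
        _, _, _, model = small_model_setup
        r = rng.normal(size=(3, 16))
        got = model.project(Tensor(r)).data
        w1, b1 = model.proj_hidden.weight.data, model.proj_hidden.bias.data
        w2, b2 = model.proj_out.weight.data, model.proj_out.bias.data
        expected = np.maximum(r @ w1 + b1, 0.0) @ w2 + b2
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_zero_vector_fully_determined_by_params(self, small_model_setup):
        _, _, _, model = small_model_setup
        z = model.project(Tensor(np.zeros((1, 16)))).data
        w2, b2 = model.proj_out.weight.data, model.proj_out.bias.data
        expected = np.maximum(model.proj_hidden.bias.data, 0.0) @ w2 + b2
        np.testing.assert_allclose(z[0], expected, atol=1e-12)


@pytest.fixture(scope="module")
def pretrained(toy_corpus_100):
    cfg = ContrastiveConfig(
        embed_dim=32, encoder_layers=1, attention_heads=2, ff_dim=64,
        proj_hidden_dim=32, proj_out_dim=16, batch_molecules=16,
        max_epochs=4, patience=4, learning_rate=2e-3, max_len=80,
        validation_fraction=0.1,
    )
    return pretrain(toy_corpus_100, cfg, seed=0, log=None)


class TestPretrain:

    def test_training_loss_decreases(self, pretrained):
        hist = pretrained.metadata["history"]
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_checkpoint_round_trip(self, pretrained, tmp_path):
        p1 = tmp_path / "a.ckpt"
        p2 = tmp_path / "b.ckpt"
        pretrained.save(p1)
        loaded = type(pretrained).load(p1)
        loaded.save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_extract_embedding_shape(self, pretrained):
        table, vocab = extract_embedding(pretrained)
        assert table.shape[0] == vocab.size
        assert table.shape[1] == pretrained.config["embed_dim"]

    def test_extract_then_reinsert_round_trip(self, pretrained, toy_corpus_100):
        model, vocab = contrastive.load_model(pretrained)
        seqs = [tokenize(toy_corpus_100[0].canonical, vocab)]
        ids, mask = pad_batch(seqs)
        before = model.encode_views(ids, mask).data
        table, _ = extract_embedding(pretrained)
        fresh, _ = contrastive.load_model(pretrained)
        fresh.encoder.tok_emb.weight.data = table.copy()
        after = fresh.encode_views(ids, mask).data
        np.testing.assert_allclose(before, after)

    def test_wrong_kind_rejected(self, pretrained):
        bad = type(pretrained)(
            kind="generator", state=pretrained.state, config=pretrained.config,
            vocab_tokens=pretrained.vocab_tokens,
        )
        with pytest.raises(CheckpointError):
            extract_embedding(bad)

    def test_seeded_determinism(self):
        from contramol.fixtures import make_toy_smiles_corpus

        corpus = make_toy_smiles_corpus(30, seed=5)
        cfg = ContrastiveConfig(
            embed_dim=16, encoder_layers=1, attention_heads=2, ff_dim=32,
            proj_hidden_dim=16, proj_out_dim=8, batch_molecules=8,
            max_epochs=2, patience=2, max_len=80,
        )
        a = pretrain(corpus, cfg, seed=3, log=None)
        b = pretrain(corpus, cfg, seed=3, log=None)
        assert a.metadata["best_val_loss"] == b.metadata["best_val_loss"]
        for key in a.state:
            np.testing.assert_array_equal(a.state[key], b.state[key])

    def test_empty_corpus_rejected(self, tiny_contrastive_config):
        with pytest.raises(ValueError):
            pretrain([], tiny_contrastive_config, seed=0, log=None)
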