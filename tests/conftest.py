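import numpy as np
import pytest

from contramol.contrastive import ContrastiveConfig
from contramol.cpi import CPIConfig
from contramol.fixtures import make_toy_smiles_corpus
from contramol.generator import DecoderConfig


@pytest.fixture(scope="session")
def toy_corpus_100():
    return make_toy_smiles_corpus(100, seed=11)


@pytest.fixture(scope="session")
def toy_corpus_500():
    return make_toy_smiles_corpus(500, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_contrastive_config():
    return ContrastiveConfig(
        embed_dim=32, encoder_layers=2, attention_heads=2, ff_dim=64,
        proj_hidden_dim=32, proj_out_dim=16, temperature=0.1,
        batch_molecules=8, max_epochs=3, patience=3, learning_rate=1e-3,
        max_len=80,
    )


@pytest.fixture
def tiny_decoder_config():
    return DecoderConfig(
        n_blocks=2, d_model=32, d_ff=64, attention_heads=2, max_len=80,
        dropout=0.0, learning_rate=1e-3, batch_size=32, max_epochs=3,
        patience=3,
    )


@pytest.fixture
def tiny_cpi_config():
    return CPIConfig(
        d_model=32, d_ff=64, n_layers=1, attention_heads=2, dropout=0.0,
        smiles_max_len=80, protein_max_len=80, batch_size=32,
        learning_rate=1e-3, max_epochs=2, patience=2,
    )
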