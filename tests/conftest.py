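import numpy as np
import pytest

from promoter70.encoders import EncoderConfig
from promoter70.pipeline import fit_chain
from promoter70.seqio import WINDOW_LEN, NucleotideSequence
from promoter70.synth import SynthConfig, make_dataset

BASES = "ACGT"


def random_seq(rng, length=WINDOW_LEN, ident="r"):
    return NucleotideSequence(ident, "".join(BASES[c] for c in rng.integers(0, 4, length)))


@pytest.fixture(scope="session")
def cfg():
    return EncoderConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def synth_small():
    """Small planted-motif dataset shared across tests."""
    return make_dataset(SynthConfig(n_pos=60, n_neg=60, seed=7))


@pytest.fixture(scope="session")
def trained_model(cfg):
    """A full-chain SVM model trained on a moderate synthetic dataset; shared
    by the application-mode and end-to-end tests."""
    pos, neg, _ = make_dataset(SynthConfig(n_pos=150, n_neg=150, seed=21))
    return fit_chain(pos, neg, cfg, kind="SVM", n_features=200, step=10, seed=5)
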