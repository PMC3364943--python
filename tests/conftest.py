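import numpy as np
import pytest
from hypothesis import settings

from structage import potential as pt
from structage import synthetic as syn
from structage.homology import AgeClass

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

AGES3 = (AgeClass.eukarya, AgeClass.metazoa, AgeClass.vertebrata)


def make_corpus(n, seed, length_range=(80, 160)):
    """Mixed-age synthetic structure corpus."""
    rng = np.random.default_rng(seed)
    corpus = []
    for k in range(n):
        cfg = syn.config_for_age(
            AGES3[k % 3],
            chain_length=int(rng.integers(*length_range)),
            seed=int(rng.integers(2**31)),
        )
        corpus.append(syn.generate_toy_structure(cfg))
    return corpus


@pytest.fixture(scope="session")
def trained_model():
    """A four-body potential trained on a 60-structure synthetic corpus."""
    return pt.train_potential(make_corpus(60, seed=424242))


@pytest.fixture(scope="session")
def toy_structure():
    return syn.generate_toy_structure(syn.SimulationConfig(chain_length=120, seed=99))
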