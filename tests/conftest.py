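"""Shared fixtures: vocabularies, tiny model states, fixture corpora.

Expensive trained models are session-scoped so the cost is paid once.
"""

import numpy as np
import pytest

from molcanvas.blm import ModelConfig, init_params
from molcanvas.chemstrings import moses_smiles_vocabulary
from molcanvas.workbench import FixtureSpec, fixture_corpus


@pytest.fixture(scope="session")
def moses_vocab():
    return moses_smiles_vocabulary()


@pytest.fixture(scope="session")
def tiny_state(moses_vocab):
    """An untrained small model over the MOSES SMILES vocabulary."""
    cfg = ModelConfig(n_layers=2, d_model=32, n_heads=4, max_len=64, seed=11)
    return init_params(moses_vocab, cfg)


@pytest.fixture(scope="session")
def packaged_corpus():
    return fixture_corpus(FixtureSpec(100, seed=3, source="packaged_list"))


@pytest.fixture(scope="session")
def random_selfies_corpus():
    return fixture_corpus(FixtureSpec(120, seed=4, source="random_selfies",
                                      max_tokens=16))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
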