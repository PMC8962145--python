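import numpy as np
import pytest

from molopt.dataset_builder import prepare_corpus
from molopt.fixtures import FixtureConfig, generate_corpus


@pytest.fixture(scope="session")
def fixture_config():
    return FixtureConfig(n_publications=20, seed=11)


@pytest.fixture(scope="session")
def corpus_and_library(fixture_config):
    return generate_corpus(fixture_config)


@pytest.fixture(scope="session")
def corpus(corpus_and_library):
    return prepare_corpus(corpus_and_library[0])


@pytest.fixture(scope="session")
def library(corpus_and_library):
    return corpus_and_library[1]


@pytest.fixture(scope="session")
def corpus_smiles(corpus):
    return sorted({rec.smiles for rec in corpus})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
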