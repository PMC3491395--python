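import pytest

from psidr.pipeline import decorate_corpus
from psidr.simulate import SimulationConfig, simulate_corpus


@pytest.fixture(scope="session")
def corpus():
    """Default synthetic corpus (noise-free planted signal), seed 1."""
    return simulate_corpus(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def decoration(corpus):
    """Full pipeline output on the default corpus."""
    return decorate_corpus(corpus)


@pytest.fixture(scope="session")
def surveyed_truth(corpus):
    truth = corpus.truth.set_index("id")
    return truth[truth.surveyed]
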