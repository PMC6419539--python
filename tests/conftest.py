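import pytest

from helpers import tiny_config

from litcohesion import cohesion, corpus_lsi, synthetic_data as sd


@pytest.fixture(scope="session")
def tiny_corpus_truth():
    return sd.generate_corpus(tiny_config())


@pytest.fixture(scope="session")
def tiny_space(tiny_corpus_truth):
    corpus, _ = tiny_corpus_truth
    return corpus_lsi.build_space(corpus, rank=60, seed=0)


@pytest.fixture(scope="session")
def tiny_threshold(tiny_space):
    return cohesion.estimate_threshold(tiny_space, cohesion.LPvConfig(seed=0))
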