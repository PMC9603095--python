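import pytest
from hypothesis import HealthCheck, settings

from rlpcascade import RLPCascade, build_benchmark

settings.register_profile(
    "default",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic corpus: 16 subfamilies x 24 RLK + 24 RLP, plus
    four background groups sized for three disjoint negative splits."""
    return build_benchmark(seed=0)


@pytest.fixture(scope="session")
def stage_sets(default_corpus):
    model = RLPCascade.from_corpus(default_corpus)
    return model.build_training_sets(seed=0)


@pytest.fixture(scope="session")
def trained(default_corpus):
    """Fully fitted cascade on the default corpus (shared across tests)."""
    model = RLPCascade.from_corpus(default_corpus)
    return model.fit(seed=0)
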