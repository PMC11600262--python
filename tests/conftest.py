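import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_bundle():
    """Seeded 20/8/4-document corpus shared across tests."""
    from litreg.simulate import GeneratorConfig, generate_corpus

    return generate_corpus(
        GeneratorConfig(seed=3, n_train=20, n_test=8, n_validation=4)
    )


@pytest.fixture(scope="session")
def tiny_ner(small_bundle):
    """Tagger trained to convergence on the small train split."""
    from litreg.ner import NerConfig, train_ner

    return train_ner(small_bundle.splits["train"], NerConfig(epochs=40, seed=5))


@pytest.fixture(scope="session")
def tiny_re(small_bundle):
    from litreg.relations import ReConfig, train_re

    return train_re(small_bundle.splits["train"], ReConfig(epochs=60, seed=6))
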