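import pytest
from hypothesis import settings

from moclokit import default_grammar, generate_toy_kit, toy_grammar

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def dg():
    return default_grammar()


@pytest.fixture(scope="session")
def tg():
    return toy_grammar()


@pytest.fixture(scope="session")
def kit():
    """One deterministic toy kit shared across the suite."""
    return generate_toy_kit(seed=1)


@pytest.fixture(scope="session")
def bsai(dg):
    return dg.enzyme_cassette


@pytest.fixture(scope="session")
def bsmbi(dg):
    return dg.enzyme_entry
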