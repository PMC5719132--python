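import pytest

from hessbond.oracle import standard_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """All named toy systems, built once per session."""
    return standard_fixtures()


@pytest.fixture(scope="session")
def diatomic(fixtures):
    return fixtures["diatomic"]


@pytest.fixture(scope="session")
def bent(fixtures):
    return fixtures["bent_triatomic"]


@pytest.fixture(scope="session")
def linear(fixtures):
    return fixtures["linear_triatomic"]


@pytest.fixture(scope="session")
def disjoint(fixtures):
    return fixtures["disjoint"]
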