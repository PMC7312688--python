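import pytest

from mitokit.synthetic import generate_genome


@pytest.fixture(scope="session")
def default_genome():
    """One shared synthetic genome with its ground-truth manifest."""
    return generate_genome(seed=101, length=60_000)


@pytest.fixture(scope="session")
def record(default_genome):
    return default_genome[0]


@pytest.fixture(scope="session")
def truth(default_genome):
    return default_genome[1]
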