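import pytest

from moonprobe import default_fixture_spec, generate_genome


@pytest.fixture(scope="session")
def fixture_spec():
    return default_fixture_spec(seed=7)


@pytest.fixture(scope="session")
def fixture_genome(fixture_spec):
    return generate_genome(fixture_spec)


@pytest.fixture(scope="session")
def genes(fixture_genome):
    return fixture_genome[0]


@pytest.fixture(scope="session")
def truth(fixture_genome):
    return fixture_genome[1]
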