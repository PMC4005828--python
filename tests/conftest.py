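import pytest

from inchilink.fixtures import FixtureSpec, gen_linked_databases
from inchilink.linkqc import EntryCorpus


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def scenario(spec):
    """One deterministic planted scenario shared across tests."""
    return gen_linked_databases(spec, seed=7)


@pytest.fixture(scope="session")
def corpus(scenario):
    return EntryCorpus(list(scenario.entries_a) + list(scenario.entries_b))
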