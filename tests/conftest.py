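import pytest

from gdamine.extract import Extractor
from gdamine.fixtures import FixtureSpec, generate_corpus
from gdamine.nlp import get_engine
from gdamine.omim import parse_entry


@pytest.fixture(scope="session")
def engine():
    return get_engine()


@pytest.fixture(scope="session")
def extractor(engine):
    return Extractor(engine=engine)


@pytest.fixture(scope="session")
def seed7_corpus():
    """The 200-entry generated corpus used by end-to-end checks."""
    return generate_corpus(FixtureSpec(seed=7, n_entries=200))


@pytest.fixture(scope="session")
def seed7_entries(seed7_corpus):
    return [parse_entry(raw) for raw in seed7_corpus.entries]
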