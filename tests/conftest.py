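import pytest

from phenocr.fixtures import fixture_gold_corpus, fixture_store
from phenocr.ontology import assign_categories, build_lexicon
from phenocr.recognizer import build_index


@pytest.fixture(scope="session")
def store():
    return fixture_store()


@pytest.fixture(scope="session")
def lexicon(store):
    return build_lexicon(store)


@pytest.fixture(scope="session")
def index(store, lexicon):
    return build_index(lexicon, store=store)


@pytest.fixture(scope="session")
def category_map(store):
    return assign_categories(store)


@pytest.fixture(scope="session")
def gold_corpus():
    return fixture_gold_corpus()
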