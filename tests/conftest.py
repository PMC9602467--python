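import numpy as np
import pytest

from cogtext import synthetic
from cogtext.lexicon import StopwordList, SynonymLexicon


@pytest.fixture(scope="session")
def templates():
    return synthetic.default_templates()


@pytest.fixture(scope="session")
def vocabulary(templates):
    return synthetic.corpus_vocabulary(templates)


@pytest.fixture(scope="session")
def fixture_lexicon(vocabulary):
    return synthetic.generate_fixture_lexicon(vocabulary, synonyms_per_word=3, seed=7)


@pytest.fixture(scope="session")
def fixture_stopwords(vocabulary):
    return synthetic.generate_fixture_stopwords(vocabulary, fraction=0.1)


@pytest.fixture(scope="session")
def default_corpus():
    """The default study-structure corpus: 45 HC + 15 MCI subjects x 12 tasks."""
    return synthetic.generate_default_corpus(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def toy_lexicon():
    return SynonymLexicon.from_dict(
        {"dog": {"puppy", "hound"}, "walk": {"stroll"}, "cat": {"kitten"}}
    )


@pytest.fixture
def toy_stopwords():
    return StopwordList(words=frozenset({"the", "a", "and"}), source_name="toy")
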