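import pytest

from trigrec.features import FAMILIES, ModelConfiguration
from trigrec.fixtures import FixtureSpec, worked_example_fixture, generate_corpus


@pytest.fixture()
def example_doc():
    return worked_example_fixture()


@pytest.fixture()
def example_sentence(example_doc):
    return example_doc.sentences[0]


@pytest.fixture(scope="session")
def small_corpus():
    """20 documents / 80 sentences; enough signal for quick CRF checks."""
    return generate_corpus(
        FixtureSpec(n_documents=20, sentences_per_doc=4, seed=13)
    )


@pytest.fixture(scope="session")
def study_corpus():
    """The study-scale synthetic corpus: 2 event types, ~300 sentences,
    20% lexical noise."""
    return generate_corpus(FixtureSpec(seed=42))


@pytest.fixture()
def full_config():
    return ModelConfiguration(
        event_type="Gene_expression",
        active_features=set(FAMILIES) - {"dictionary"},
        context_mode="conjunctions",
    )
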