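import pytest

from lcscoder.fixtures import paper_fixtures


@pytest.fixture(scope="session")
def fx():
    """The bundled worked examples (SDL, ontology, similarity table)."""
    return paper_fixtures()
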