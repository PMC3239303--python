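import io

import pytest

import regevents as rg


@pytest.fixture(scope="session")
def ont():
    return rg.default_ontology()


@pytest.fixture(scope="session")
def patterns(ont):
    return rg.default_patterns(ont)


@pytest.fixture(scope="session")
def rules(ont):
    return rg.default_rules(ont)


@pytest.fixture(scope="session")
def templates(ont):
    return rg.default_templates(ont)


def make_dictionary(rows, ont, **kwargs):
    """Build a Dictionary from (surface, id, labels) tuples."""
    text = "\n".join("\t".join(row) for row in rows)
    return rg.load_dictionary(io.StringIO(text), ont, **kwargs)


@pytest.fixture()
def dict_of():
    return make_dictionary
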