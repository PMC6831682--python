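import pytest

from phonofluency import load_default_lexicon, load_default_mapping


@pytest.fixture(scope="session")
def mapping():
    return load_default_mapping()


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def parse(mapping):
    return mapping.parse
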