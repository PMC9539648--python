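import pytest

from carelex import ClassifierConfig, bundled_fixture_lexicon


@pytest.fixture(scope="session")
def lex():
    return bundled_fixture_lexicon()


@pytest.fixture(scope="session")
def cfg(lex):
    return ClassifierConfig(lexicon=lex)
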