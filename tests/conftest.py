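import pytest

from lingfcm import datasets


@pytest.fixture(scope="session")
def kb():
    return datasets.load_knowledge_base()


@pytest.fixture(scope="session")
def lexicon():
    return datasets.load_lexicon()


@pytest.fixture(scope="session")
def heart_map():
    return datasets.load_heart_disease_map()


@pytest.fixture(scope="session")
def homeless_map():
    return datasets.load_homelessness_map()
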