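from pathlib import Path

import pytest

import egfrtext as E

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def lexicon():
    return E.default_lexicon()


@pytest.fixture(scope="session")
def grammar():
    return E.default_grammar()


@pytest.fixture(scope="session")
def base_grammar():
    return E.packaged_grammar("egfr_base")


@pytest.fixture(scope="session")
def noext_grammar():
    return E.packaged_grammar("egfr_noext")


@pytest.fixture(scope="session")
def dialects():
    return E.load_dialects()


@pytest.fixture(scope="session")
def sample_rtf():
    return (DATA_DIR / "sample_report.rtf").read_text(encoding="utf-8")
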