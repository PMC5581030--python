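import pytest

from melchip import build_layout, load_codon_contexts, load_default_panel


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def layout(panel):
    return build_layout(panel)


@pytest.fixture(scope="session")
def contexts():
    return load_codon_contexts()
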