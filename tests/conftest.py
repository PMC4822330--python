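import pytest

from nmhistone.homology import load_panel
from nmhistone.ptm_catalog import load_catalog


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()
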