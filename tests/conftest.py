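import pytest

from speciescall import PanelArrays, synthetic_reference_panel, tp1_panel


@pytest.fixture(scope="session")
def tp1():
    return tp1_panel()


@pytest.fixture(scope="session")
def tp1_arrays(tp1):
    return PanelArrays(tp1)


@pytest.fixture(scope="session")
def ref_panel():
    return synthetic_reference_panel()


@pytest.fixture(scope="session")
def ref_arrays(ref_panel):
    return PanelArrays(ref_panel)
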