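import numpy as np
import pytest

from editscan.aligncount import AmpliconIndex
from editscan.panel import example_panel, make_sample_sheet


@pytest.fixture(scope="session")
def fixture_panel():
    panel, sheet = example_panel()
    return panel


@pytest.fixture(scope="session")
def fixture_sheet():
    _, sheet = example_panel()
    return sheet


@pytest.fixture(scope="session")
def fixture_index(fixture_panel):
    return AmpliconIndex(fixture_panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_sheet():
    return make_sample_sheet(n_ad=2, n_ndc=2, tissue="HpC", seed=7)
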