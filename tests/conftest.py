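import numpy as np
import pytest

from riverscape.dec import DECParams
from riverscape.geography import build_lem, stepping_stone_chain


@pytest.fixture
def lem2():
    """Two fully connected areas A, B."""
    return build_lem(
        {"name": "full2", "regions": ["A", "B"], "adjacency": [[0, 1], [1, 0]]}
    )


@pytest.fixture
def chain4():
    """Four-region stepping-stone chain A-B-C-D."""
    return stepping_stone_chain(list("ABCD"), name="chain4")


@pytest.fixture
def fig4_lem():
    """Seven bioregions with the field's single-letter codes, fully connected."""
    codes = list("BGLNOTW")
    adj = [[0 if i == j else 1 for j in range(7)] for i in range(7)]
    return build_lem({"name": "seven", "regions": codes, "adjacency": adj})


@pytest.fixture
def params_small():
    return DECParams(delta=0.1, e=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
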