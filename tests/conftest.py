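import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import vascnet as vn


@pytest.fixture(scope="session")
def truth_graph():
    """A medium synthetic tube network used across extraction tests."""
    return vn.generate_tube_network(14, 256, 256, seed=1)


@pytest.fixture(scope="session")
def clean_scene(truth_graph):
    return vn.render_scene(truth_graph, tube_width=5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
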