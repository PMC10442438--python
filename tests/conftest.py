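import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fiberphot.behavior import MazeGeometry
from fiberphot.photometry import DffTrace


@pytest.fixture
def epm():
    return MazeGeometry("EPM")


@pytest.fixture
def oft():
    return MazeGeometry("OFT")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(values, rate=20.0):
    values = np.asarray(values, float)
    return DffTrace(t=np.arange(len(values)) / rate, values=values, rate=rate)
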