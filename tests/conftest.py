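import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from patcomplex import pattern_sim


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def four_axis_pattern():
    return pattern_sim.generate_class("4-axes", seed=11)


@pytest.fixture(scope="session")
def vertical_pattern():
    return pattern_sim.generate_class("1-orthogonal", seed=7)


@pytest.fixture(scope="session")
def asymmetric_pattern():
    return pattern_sim.generate_class("asymmetric", seed=5)
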