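import numpy as np
import pytest

from rootsim.core_mesh import build_root_grid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    """3 columns x 5 rows, uniform 10x12 µm cells; 2 growable rows."""
    return build_root_grid(3, 5, [10.0, 10.0, 10.0], row_height=12.0)


@pytest.fixture
def grid12():
    """The standard 12-file starter grid (narrow inner files)."""
    return build_root_grid(12, 4)
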