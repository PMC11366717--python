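import numpy as np
import pytest

from sacsim.cell.protocols import CellParams, init_and_prepace


@pytest.fixture(scope="session")
def baseline_cell_state():
    """Scale-1 cell prepaced 50 beats at BCL 500 ms (shared, read-only)."""
    return init_and_prepace(CellParams(), 500.0, 50)


@pytest.fixture(scope="session")
def baseline_params():
    return CellParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
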