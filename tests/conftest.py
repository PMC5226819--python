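import warnings

import numpy as np
import pytest

from cawave import (CellParams, StimulusParams, build_dense_grid,
                    field_homogeneous, simulate, SimulationConfig)


@pytest.fixture(scope="session")
def params():
    return CellParams()


@pytest.fixture(scope="session")
def grid_5x5():
    return build_dense_grid(5, 5)


@pytest.fixture(scope="session")
def grid_25x25():
    return build_dense_grid(25, 25)


@pytest.fixture(scope="session")
def single_cell_default():
    """Reference single-cell run: sustained oscillation regime, 600 s."""
    g = build_dense_grid(1, 1)
    f = field_homogeneous(g, StimulusParams(60.0, 1.8, 0.9))
    return simulate(SimulationConfig(g, f, t_end=600.0))


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* samples for .* bins")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
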