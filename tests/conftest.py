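import numpy as np
import pytest

from grnsim import workflow


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy5():
    """The five-gene exemplar at study scale: 500 cells, 500 simulated hours."""
    return workflow.make_fixture("toy5", seed=0, n_cells=500)


@pytest.fixture(scope="session")
def toy5_small():
    """A cheap toy-network run for shape/determinism checks."""
    return workflow.make_fixture("toy5", seed=1, n_cells=40, t_end=30.0)
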