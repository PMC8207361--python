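import numpy as np
import pytest

from fishscape.engine import GridLevels, run_scenario_grid

REDUCED_SEED = 0
REDUCED_REPLICATES = 10
REDUCED_KS = (5, 40, 160)


@pytest.fixture(scope="session")
def reduced_grid_summaries():
    """A scaled-down factorial experiment shared across analysis tests.

    Ten replicates per scenario over all six fishing levels, both
    preference modes, both landscapes and the low/middle/high carrying
    capacities; enough replication for the qualitative slope structure
    while keeping the suite fast.
    """
    levels = GridLevels(carrying_capacities=REDUCED_KS)
    return run_scenario_grid(
        levels, replicates=REDUCED_REPLICATES, master_seed=REDUCED_SEED
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
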