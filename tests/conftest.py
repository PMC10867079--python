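import numpy as np
import pytest

from rdmc.model_core import DMCParameters, RDMCParameters
from rdmc.presets import RDMC_PRESETS
from rdmc.simulator import simulate_dataset


@pytest.fixture(scope="session")
def table3_row1() -> RDMCParameters:
    """Slow congruent attention shift: the negative-going delta preset."""
    return RDMC_PRESETS["table3-row1"]


@pytest.fixture(scope="session")
def dmc_demo_params() -> DMCParameters:
    return DMCParameters(A=20.0, tau=30.0, alpha=2.0, v_c=0.7,
                         a=100.0, sigma=3.0, Ter=310.0, st=80.0)


@pytest.fixture(scope="session")
def small_table(table3_row1):
    """A modest simulated dataset shared by summary/fitting tests."""
    return simulate_dataset(table3_row1, 400, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
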