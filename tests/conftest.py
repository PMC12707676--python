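from dataclasses import replace

import pytest

from branchcycle.distributions import TimeGrid
from branchcycle.params import (MODEL1_BASELINE, MODEL2_BASELINE, MODEL1_G2M,
                                MODEL2_G2M, MODEL3_S)


@pytest.fixture(scope="session")
def base2():
    """Model 2 (H460 NSCLC) baseline, truncated at 7 generations."""
    return replace(MODEL2_BASELINE, n_gen=7)


@pytest.fixture(scope="session")
def base1():
    return replace(MODEL1_BASELINE, n_gen=7)


@pytest.fixture(scope="session")
def g2m_params():
    return MODEL2_G2M


@pytest.fixture(scope="session")
def s_params():
    return MODEL3_S


@pytest.fixture(scope="session")
def grid():
    return TimeGrid(0.1, 60.0)


@pytest.fixture(scope="session")
def grid72():
    return TimeGrid(0.1, 72.0)
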