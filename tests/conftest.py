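import numpy as np
import pytest

from afdsim.acquisition import make_paper_scheme
from afdsim.biophysics import KERNEL_PARAMS, analytic_response
from afdsim.cohort import CohortSpec, generate_cohort
from afdsim.simstudy import SimulationGrid, run_grid


@pytest.fixture(scope="session")
def paper_scheme():
    return make_paper_scheme()


@pytest.fixture(scope="session")
def kernel_response(paper_scheme):
    return analytic_response(KERNEL_PARAMS, paper_scheme, l_max=8)


@pytest.fixture(scope="session")
def noiseless_grid():
    """The full noiseless 42-combination x 5-scheme AFD table."""
    return run_grid(SimulationGrid(), seed=0)


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort with the shipped R² targets."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20200326)
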