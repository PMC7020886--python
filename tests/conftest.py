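import warnings

import numpy as np
import pytest

from gradedcat import CohortSpec, reference_bank, simulate_responses
from gradedcat.calibration import EMConfig, fit_model


@pytest.fixture(scope="session")
def ref_bank():
    return reference_bank()


@pytest.fixture(scope="session")
def cohort(ref_bank):
    """1000-person cohort simulated from the reference bank (seed 2)."""
    responses, thetas = simulate_responses(ref_bank, CohortSpec(n_persons=1000, seed=2))
    return responses, thetas


@pytest.fixture(scope="session")
def calibrated(cohort):
    """GRM calibration of the session cohort (shared across tests)."""
    responses, _ = cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model(responses, "GRM", EMConfig(tol=5e-4, max_cycles=200))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
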