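import numpy as np
import pytest

from lungtraj.simulate import fvc_reference_params, simulate_cohort


@pytest.fixture(scope="session")
def fvc_truth():
    return fvc_reference_params()


@pytest.fixture(scope="session")
def toy_cohort(fvc_truth):
    """Five patients at the reference FVC truth; shared across oracle tests."""
    return simulate_cohort(fvc_truth, 5, np.random.default_rng(3))


@pytest.fixture(scope="session")
def small_cohort(fvc_truth):
    """A 200-patient cohort for descriptive/summary checks."""
    return simulate_cohort(fvc_truth, 200, np.random.default_rng(42))
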