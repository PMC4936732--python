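import numpy as np
import pytest
from hypothesis import settings

from tbiroc import generator as gen
from tbiroc.schema import crash_schema

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schema():
    return crash_schema()


@pytest.fixture(scope="session")
def truth():
    """Uncalibrated default generative model."""
    return gen.default_truth(seed=0)


@pytest.fixture(scope="session")
def calibrated(truth):
    """Default model calibrated to the published frequency table."""
    return gen.calibrate(truth)


@pytest.fixture(scope="session")
def cohort_4k(calibrated):
    """Complete-case synthetic cohort of 4000 records."""
    return gen.sample_cohort(calibrated, 4000, seed=101)


@pytest.fixture(scope="session")
def planted_cohort():
    """n=5000, two informative predictors (v01, v02) among ten."""
    model = gen.planted_model(10, {"v01": 2.0, "v02": 1.5}, seed=0)
    return gen.sample_cohort(model, 5000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
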