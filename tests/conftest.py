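import warnings

import numpy as np
import pytest

from agegaps.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort350():
    """Default study-scale cohort with its generative truth."""
    return generate_cohort(GeneratorConfig(n=350), seed=0)


@pytest.fixture(scope="session")
def cohort5000():
    """Large cohort for population-level calibration checks."""
    return generate_cohort(GeneratorConfig(n=5000), seed=11)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n=.*<= p=.*")
        warnings.filterwarnings("ignore", message=".*fewer than 100 iterations.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
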