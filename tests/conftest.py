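import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic 104-specimen landmark dataset under the study design."""
    from equilunge.synthetic import generate_landmark_dataset

    return generate_landmark_dataset(seed=7)


@pytest.fixture(scope="session")
def default_fit(default_dataset):
    from equilunge.gpa import gpa

    return gpa(default_dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
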