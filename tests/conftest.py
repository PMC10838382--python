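import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from effluxkit.simulate import SyntheticTruth, ViabilityTruth

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def truth():
    """Study-condition ground truth with a fixed seed."""
    return SyntheticTruth(seed=0)


@pytest.fixture
def quiet_truth():
    """Noiseless viability truth for exact parameter-recovery checks."""
    return SyntheticTruth(seed=0, viability=ViabilityTruth(ic50=2e-9, hill=1.5,
                                                           noise_cv=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
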