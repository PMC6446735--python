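import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from cuelpp.config import DEFAULT_CONFIG
from cuelpp.data_model import EpochSet, SensorMontage, default_montage


@pytest.fixture(scope="session")
def small_montage() -> SensorMontage:
    return default_montage(16, 4)


@pytest.fixture(scope="session")
def full_montage() -> SensorMontage:
    return default_montage()


@pytest.fixture()
def toy_epochs(small_montage) -> EpochSet:
    """4 quiet epochs (2 categories) on the small montage."""
    rng = np.random.default_rng(11)
    n = DEFAULT_CONFIG.n_epoch_samples
    t = DEFAULT_CONFIG.epoch_window_ms[0] + np.arange(n) * 4.0
    data = rng.normal(0.0, 1.0, size=(4, small_montage.n_sensors, n))
    cats = np.array(["neutral", "erotica", "neutral", "erotica"], dtype=object)
    return EpochSet(data, t, cats, small_montage, participant_id="toy")
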