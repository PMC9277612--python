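import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import intertidal as it
from intertidal.synth import SyntheticConfig, generate_all

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sj_profile():
    """The published SJ transect (9 sites, −15..150 cm)."""
    return it.load_transect("SJ")


@pytest.fixture(scope="session")
def threshold_model():
    """Feedback law calibrated from the published regime boundaries."""
    return it.calibrate_from_thresholds(150.0, 4.57, -15.0, 8.14)


@pytest.fixture(scope="session")
def synthetic_tables():
    """One seeded synthetic study (all four tables), shared read-only."""
    return generate_all(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_tables():
    """Noiseless synthetic study for exact round-trip checks."""
    cfg = SyntheticConfig(seed=7, pin_noise_sd_mm=0.0, marker_noise_sd_mm=0.0)
    return generate_all(cfg, include_quadrats=False)
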