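import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nichescreen import FieldSpec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec() -> FieldSpec:
    """A fast noise-free field: 2 colonies, 50 cancer cells, 100 CAFs."""
    return FieldSpec(
        width_px=400, height_px=400, n_caf=100, n_cancer=50,
        csc_fraction=0.4, n_colonies=2, colony_radius_um=150.0,
        noise_sd=(0.0, 0.0, 0.0), seed=7,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
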