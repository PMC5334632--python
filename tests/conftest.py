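import pytest
from hypothesis import HealthCheck, settings

from apascreen.library import curated_library
from apascreen.simulate import CohortSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lib():
    return curated_library()


@pytest.fixture()
def clean_spec():
    """Noise-free generator settings: no jitter, no background, no noise."""
    return CohortSpec(
        mz_jitter_ppm_sd=0.0,
        rt_jitter_sd=0.0,
        n_background_features=0,
        noise_peak_rate=0.0,
    )


@pytest.fixture()
def small_cohort_spec():
    """A reduced cohort for fast structural tests."""
    return CohortSpec(
        seed=7,
        n_samples=6,
        apa_sample_ids=("S1", "S3"),
        n_background_features=150,
        noise_peak_rate=5.0,
    )
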