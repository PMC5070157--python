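import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """Default-parameter synthetic cohort at the study's sample size."""
    from gfrbench import generate_cohort

    return generate_cohort(n=245, seed=20160345)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Cohort with all noise terms zeroed: markers exactly invert the
    CKD-EPI equations and measured GFR equals the latent truth."""
    from gfrbench import generate_cohort

    return generate_cohort(n=150, seed=7, marker_noise_sd=0.0, mgfr_noise_sd=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
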