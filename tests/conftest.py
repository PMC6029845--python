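import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """Small cohort with clear identity and categorical components."""
    from megfusion.synthgen import Envelope, SyntheticSpec

    return SyntheticSpec(
        n_subjects=2,
        n_conditions=4,
        n_trials_per_condition=9,
        n_channels=16,
        time_start_ms=0.0,
        time_stop_ms=250.0,
        noise_sd=0.8,
        identity_envelope=Envelope(
            onset_ms=40.0, peak_ms=100.0, fwhm_ms=80.0, amplitude=1.0
        ),
        category_envelope=Envelope(
            onset_ms=90.0, peak_ms=170.0, fwhm_ms=80.0, amplitude=0.8
        ),
        seed=1234,
    )
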