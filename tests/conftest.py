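import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from breath4dct import SyntheticSpec, generate_signal

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def regular_signal():
    """Noise-free, drift-free, perfectly periodic breathing (4 s, 25 Hz)."""
    spec = SyntheticSpec(
        duration_s=240.0,
        period_sd_s=0.0,
        amp_sd=0.0,
        noise_sd=0.0,
        drift_slope=0.0,
        seed=11,
        curve_id="regular",
    )
    return generate_signal(spec)


@pytest.fixture(scope="session")
def irregular_signal():
    """Variable amplitude/period with one long pause and mild noise."""
    spec = SyntheticSpec(
        duration_s=240.0,
        period_sd_s=0.4,
        amp_sd=0.3,
        noise_sd=0.02,
        pauses=[(12, 9.0)],
        seed=29,
        curve_id="irregular",
    )
    return generate_signal(spec)
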