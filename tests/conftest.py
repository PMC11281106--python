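import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trunksway.config import RunConfig
from trunksway.synthetic import (
    CohortSpec,
    RecordingTiming,
    SwayProfile,
    generate_recording,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: reduced-size study conditions: 1024-sample (10.24 s at 100 Hz) analysis
#: windows, nine windows per session, smoothing shortened proportionally.
REDUCED_WINDOW_S = 1024 / 100.0


def reduced_config(seed: int) -> RunConfig:
    return RunConfig(
        window_minutes=REDUCED_WINDOW_S / 60.0,
        session_minutes=9 * REDUCED_WINDOW_S / 60.0,
        acc_smooth_samples=15,
        min_window_samples=256,
        seed=seed,
    )


def reduced_cohort_spec(seed: int, n_pain_free: int = 6, n_csp: int = 10) -> CohortSpec:
    return CohortSpec(
        n_pain_free=n_pain_free,
        n_csp=n_csp,
        days=(1, 3, 5),
        session_minutes=9 * REDUCED_WINDOW_S / 60.0,
        window_minutes=REDUCED_WINDOW_S / 60.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def bout_recording():
    """300 s recording with 3 walking bouts, shared across detection tests."""
    return generate_recording(
        SwayProfile(walk_bouts=3),
        RecordingTiming(duration_s=300.0),
        seed=42,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
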