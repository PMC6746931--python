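import numpy as np
import pytest

from semgfeat import ExtractionConfig, ProtocolConfig, generate_recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_recording():
    """Short 4-channel protocol recording: 3 movements x 2 repetitions,
    1 s movement + 0.6 s rest at 500 Hz (fast to extract)."""
    cfg = ProtocolConfig(
        n_movements=3,
        n_repetitions=2,
        movement_duration_s=1.0,
        rest_duration_s=0.6,
        n_channels=4,
        sampling_rate_hz=500.0,
        rise_time_s=0.02,
        seed=11,
    )
    rec, truth = generate_recording(cfg)
    return rec, truth


@pytest.fixture()
def small_config():
    return ExtractionConfig(winsize=128, wininc=32, feature_name="rms")
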