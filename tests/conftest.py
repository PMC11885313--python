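import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_arat():
    """A small grasp session shared across tests: 2 arrays × 4 channels,
    60 s, clean + pause-resume + invalid candidates, event-locked gamma."""
    from strokesig.synthetic import SyntheticConfig, generate_arat_session

    cfg = SyntheticConfig(
        n_arrays=2,
        channels_per_array=4,
        duration_s=80.0,
        n_clean_closings=4,
        n_pause_resume=2,
        n_stalled=1,
        n_low_start=1,
        inter_block_hold_s=3.0,
        n_responsive=4,
        seed=7,
    )
    bundle, truth = generate_arat_session(cfg)
    return cfg, bundle, truth
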