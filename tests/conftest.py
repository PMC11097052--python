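import numpy as np
import pytest

from wristgait.simulate import Segment, SimConfig, generate_recording


@pytest.fixture(scope="session")
def rest_recording():
    cfg = SimConfig(
        schedule=(Segment("rest", 30.0, noise_sd_g=0.003),), seed=3
    )
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def gait_recording():
    """20 s rest, 30 s clean gait at 2 Hz steps (swing 0.5 g), 10 s rest."""
    cfg = SimConfig(
        schedule=(
            Segment("rest", 20.0),
            Segment("gait", 30.0, step_freq_hz=2.0, swing_amp_g=0.5),
            Segment("rest", 10.0),
        ),
        seed=1,
    )
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def gait_recording_moderate():
    """Same schedule with a moderate 0.3 g swing."""
    cfg = SimConfig(
        schedule=(
            Segment("rest", 20.0),
            Segment("gait", 30.0, step_freq_hz=2.0, swing_amp_g=0.3),
            Segment("rest", 10.0),
        ),
        seed=1,
    )
    return generate_recording(cfg)


def random_rotation(rng) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
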