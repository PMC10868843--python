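import numpy as np
import pytest

from imuknee import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_squat_trial():
    """One noise-free squat trial (5 repetitions, cohort-mean ROM)."""
    template = syn.make_template("squat", 78.85, 3.0)
    return syn.generate_trial(template, np.random.default_rng(7), repetitions=5)


@pytest.fixture(scope="session")
def identity_calibration():
    from imuknee.rotation import CalibrationRecord

    ident = np.array([1.0, 0.0, 0.0, 0.0])
    return CalibrationRecord(thigh_offset=ident, shank_offset=ident, window=(0.0, 1.0))


def constant_stream(segment, q, duration=1.0, rate=200.0):
    """Helper: a constant-orientation stream (importable from conftest)."""
    from imuknee.pipeline import OrientationStream

    n = int(duration * rate) + 1
    t = np.arange(n) / rate
    return OrientationStream(
        segment=segment, timestamps=t, quaternions=np.tile(np.asarray(q, float), (n, 1)),
        sample_rate_hz=rate,
    )
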