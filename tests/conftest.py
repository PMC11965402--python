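import numpy as np
import pytest

import rehabtrack as rt


@pytest.fixture(scope="session")
def hip_flexion_session():
    """Zero-noise 10-rep hip-flexion session with ground truth."""
    return rt.generate_session(rt.default_profile("hip_flexion"))


@pytest.fixture(scope="session")
def pose_data():
    """Well-separated synthetic up/down pose dataset with a held-out test set."""
    return rt.generate_pose_dataset(seed=1)


@pytest.fixture()
def make_trace():
    """Build an AngleTrace directly from an angle array (30 fps frames)."""

    def _make(theta):
        theta = np.asarray(theta, dtype=float)
        n = len(theta)
        return rt.AngleTrace(theta, np.arange(n), np.arange(n) / 30.0)

    return _make


@pytest.fixture()
def single_frame():
    """One schema-complete synthetic frame (leg at 120 degrees)."""
    seq, _ = rt.generate_session(
        rt.MotionProfile(exercise="hip_flexion", reps=0, theta_start=120.0, theta_end=10.0)
    )
    return seq[0]
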