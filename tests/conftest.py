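import numpy as np
import pandas as pd
import pytest

from tailkin import synthetic_data as sd
from tailkin.kinematics import FRAME_COLUMNS


def frames_from_theta(theta_deg, fps=60.0, body_scale=100.0, tail_scale=60.0,
                      heading=0.3, origin=(400.0, 300.0), conf=1.0):
    """Build a landmark table whose extracted tail angle is exactly
    ``theta_deg``: the independent geometric construction used as the
    inverse-pair oracle throughout the tests."""
    theta = np.asarray(theta_deg, dtype=float)
    n = theta.size
    t = np.arange(n) / fps
    b = np.array([np.cos(heading), np.sin(heading)])
    r = np.array([-b[1], b[0]])
    B = np.tile(np.asarray(origin, float), (n, 1))
    S = B - body_scale * b
    th = np.radians(theta)
    M = B + 0.5 * tail_scale * (b * np.cos(th)[:, None] + r * np.sin(th)[:, None])
    T = B + tail_scale * (b * np.cos(th)[:, None] + r * np.sin(th)[:, None])
    nose = S - 0.45 * body_scale * b
    head = S - 0.25 * body_scale * b
    data = {"t": t}
    for name, arr in (("nose", nose), ("front_head", head), ("shoulders", S),
                      ("tail_base", B), ("tail_middle", M), ("tail_tip", T)):
        data[f"{name}_x"] = arr[:, 0]
        data[f"{name}_y"] = arr[:, 1]
    data["conf"] = np.full(n, conf, dtype=float)
    return pd.DataFrame(data, columns=list(FRAME_COLUMNS))


@pytest.fixture(scope="session")
def small_study():
    """A 2-dog, 1-session, 4-trial study with default noise (shared across
    tests that only need labelled segments)."""
    profiles = sd.sample_dog_profiles(2, seed=5)
    design = sd.StudyDesign(n_dogs=2, sessions=1, trials_per_session=4, seed=5)
    return sd.simulate_study(profiles, design)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
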