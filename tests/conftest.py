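import json

import numpy as np
import pytest

from gaitmatch.kinematics import JointAngleSeries
from gaitmatch.synthetic import CohortConfig, make_angle_dataset, sample_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort_config():
    """Tiny cohort: keeps per-test matching runs fast."""
    return CohortConfig(n_subjects=4, views=("0", "90", "180"), n_frames=40)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return sample_cohort(small_cohort_config, seed=7)


@pytest.fixture(scope="session")
def small_angle_dataset(small_cohort_config):
    return make_angle_dataset(small_cohort_config, seed=7)


@pytest.fixture
def toy_series():
    """4-frame, 3-column angle series with known structure."""
    values = np.array([
        [10.0, 100.0, 20.0],
        [20.0, 90.0, 20.0],
        [30.0, 80.0, 20.0],
        [40.0, 70.0, 20.0],
    ])
    return JointAngleSeries(values=values, angle_names=["A", "B", "C"])


def write_mediapipe_jsonl(path, coords, visibility=None):
    """coords: (T, 33, 3) array -> MediaPipe JSON-lines file."""
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        for t in range(coords.shape[0]):
            landmarks = []
            for j in range(coords.shape[1]):
                lm = {"x": coords[t, j, 0], "y": coords[t, j, 1], "z": coords[t, j, 2]}
                if visibility is not None:
                    lm["visibility"] = float(visibility[t, j])
                landmarks.append(lm)
            fh.write(json.dumps({"frame": t, "landmarks": landmarks}) + "\n")
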