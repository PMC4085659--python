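import numpy as np
import pytest

from kinespeed.motion_io import MotionRecording
from kinespeed.synthetic import SimulationConfig, SubjectParams, simulate_cohort

ARM4 = ("SHOULDER_RIGHT", "ELBOW_RIGHT", "WRIST_RIGHT", "HAND_RIGHT")


def make_recording(hand_positions, fs=30.0, timestamps=None,
                   recording_id="rec", subject_id="S01", label="unlabeled"):
    """A 4-joint recording whose HAND follows the given (n, 3) positions;
    the other arm joints stay at distinct static points."""
    hand = np.asarray(hand_positions, dtype=float)
    n = hand.shape[0]
    if timestamps is None:
        timestamps = np.arange(n) / fs
    positions = np.empty((n, 4, 3))
    positions[:, 0] = (0.0, 1.4, 2.7)   # shoulder
    positions[:, 1] = (0.1, 1.0, 2.7)   # elbow
    positions[:, 2] = (0.2, 0.7, 2.7)   # wrist
    positions[:, 3] = hand
    return MotionRecording(
        recording_id=recording_id, subject_id=subject_id,
        dominant_side="right", joints=ARM4, timestamps=timestamps,
        positions=positions, nominal_fs=fs, label=label,
    )


def recording_from_velocity(values, fs=30.0, **kwargs):
    """A recording whose nominal-timing HAND velocity equals ``values``
    exactly (straight-line motion along x)."""
    values = np.asarray(values, dtype=float)
    T = 1.0 / fs
    x = np.concatenate([[0.0], np.cumsum(values) * T])
    hand = np.column_stack([x, np.full(x.size, 0.4), np.full(x.size, 2.7)])
    return make_recording(hand, fs=fs, **kwargs)


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(n_subjects=3, reps_per_class=2, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-size cohort for statistics-flavoured tests."""
    return simulate_cohort(SimulationConfig(n_subjects=6, reps_per_class=3,
                                            seed=11))


@pytest.fixture
def subject():
    return SubjectParams(subject_id="S01", arm_length=0.713,
                         speed_multiplier=1.0)
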