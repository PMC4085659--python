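"""Synthetic depth-camera arm-raise cohorts with known ground truth.

The generator emulates the benchmark acquisition this package targets:
subjects standing in front of a 30 Hz depth camera raise the dominant arm
from rest at the side through 135 degrees of shoulder elevation.  Each
cohort has a configurable number of subjects, each contributing several
repetitions of three instructed speed classes (slow / normal / fast).

Per recording, the dominant arm is a rigid two-segment chain rotating about
a fixed shoulder; the elevation angle follows the minimum-jerk profile
``theta(tau) = dtheta * (10 tau^3 - 15 tau^4 + 6 tau^5)``, the standard
model of voluntary point-to-point reaching.  The movement is framed by
short stationary holds (reaction to the start signal, holding the arm up
until the stop signal).  Movement duration is set analytically from the
class's target mean hand speed: ``D = hand path length / target speed``.
Sensor imperfections are i.i.d. Gaussian position noise per joint and axis
and sampling jitter modelled as truncated-Gaussian frame intervals.  The
remaining 16 skeleton joints are emitted as static points with the same
noise so files carry the full 20-joint, 60-value frame layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .motion_io import (CLASS_LABELS, KINECT_JOINTS, AnnotationRecord,
                        Dataset, MotionRecording)

__all__ = [
    "SimulationConfig",
    "SubjectParams",
    "GroundTruth",
    "draw_subjects",
    "simulate_motion",
    "simulate_cohort",
    "jitter_statistics",
]


def _default_class_speeds() -> dict[str, float]:
    # movement-phase mean hand speeds (m/s); chosen so measured mean
    # velocities straddle the canonical decision boundaries 0.58 and 1.50
    return {"slow": 0.35, "normal": 1.0, "fast": 2.0}


@dataclass
class SimulationConfig:
    """Cohort design and sensor model parameters.

    All lengths in meters, times in seconds, speeds in m/s.
    """

    n_subjects: int = 27
    reps_per_class: int = 5
    class_speeds: dict[str, float] = field(default_factory=_default_class_speeds)
    arm_length_mean: float = 0.713
    arm_length_sd: float = 0.052
    arm_length_bounds: tuple[float, float] = (0.5, 0.9)
    upper_arm_fraction: float = 0.55   # of arm length; forearm is the rest
    hand_offset: float = 0.10          # hand point beyond the wrist
    delta_theta_deg: float = 135.0
    position_noise_sd: float = 0.003
    dt_mean: float = 0.0334
    dt_sd: float = 0.0037
    dt_floor: float = 0.005
    subject_speed_sd: float = 0.08     # relative, multiplicative per subject
    shoulder_sway: float = 0.08        # scapular elevation over the raise, m
    pre_hold: float = 0.10             # stationary lead-in (signal reaction)
    post_hold: float = 0.10            # stationary hold with the arm up
    min_frames: int = 34               # pads the terminal hold if needed
    nominal_fs: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        speeds = [self.class_speeds[c] for c in CLASS_LABELS]
        if not speeds[0] < speeds[1] < speeds[2]:
            raise ValueError("class speeds must be ordered slow < normal < fast")
        positive = (self.n_subjects, self.reps_per_class, self.arm_length_mean,
                    self.arm_length_sd, self.delta_theta_deg, self.dt_mean,
                    self.dt_floor, self.nominal_fs, *speeds)
        if any(v <= 0 for v in positive):
            raise ValueError("cohort/sensor parameters must be positive")
        nonneg = (self.dt_sd, self.position_noise_sd, self.subject_speed_sd,
                  self.shoulder_sway, self.pre_hold, self.post_hold)
        if any(v < 0 for v in nonneg):
            raise ValueError("noise/jitter/hold parameters must be non-negative")
        if not 0 < self.upper_arm_fraction < 1:
            raise ValueError("upper_arm_fraction must be in (0, 1)")


@dataclass(frozen=True)
class SubjectParams:
    subject_id: str
    arm_length: float
    speed_multiplier: float
    dominant_side: str = "right"


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did for one recording."""

    recording_id: str
    subject_id: str
    label: str
    target_speed: float       # movement-phase mean hand speed, m/s
    movement_duration: float  # s, excludes holds
    total_duration: float     # s, includes holds and any padding
    arm_length: float
    n_frames: int
    seed: int


def _draw_intervals(rng: np.random.Generator, n: int,
                    config: SimulationConfig) -> np.ndarray:
    return np.maximum(rng.normal(config.dt_mean, config.dt_sd, n),
                      config.dt_floor)


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _static_skeleton(side: str, L: float) -> dict[str, np.ndarray]:
    """Rest positions of all 20 joints in the camera frame (x lateral,
    y up, z depth; subject 2.7 m from the camera)."""
    z = 2.70
    pts = {
        "HIP_CENTER": (0.00, -0.30, z), "SPINE": (0.00, -0.05, z),
        "SHOULDER_CENTER": (0.00, 0.22, z), "HEAD": (0.00, 0.45, z),
        "SHOULDER_LEFT": (-0.18, 0.22, z), "SHOULDER_RIGHT": (0.18, 0.22, z),
        "HIP_LEFT": (-0.10, -0.32, z), "HIP_RIGHT": (0.10, -0.32, z),
        "KNEE_LEFT": (-0.11, -0.75, z), "KNEE_RIGHT": (0.11, -0.75, z),
        "ANKLE_LEFT": (-0.12, -1.15, z), "ANKLE_RIGHT": (0.12, -1.15, z),
        "FOOT_LEFT": (-0.13, -1.22, z - 0.10),
        "FOOT_RIGHT": (0.13, -1.22, z - 0.10),
    }
    out = {name: np.array(p) for name, p in pts.items()}
    # both arms hang at rest; the dominant one is animated later
    for s in ("LEFT", "RIGHT"):
        shoulder = out[f"SHOULDER_{s}"]
        down = np.array([0.0, -1.0, 0.0])
        out[f"ELBOW_{s}"] = shoulder + 0.55 * L * down
        out[f"WRIST_{s}"] = shoulder + L * down
        out[f"HAND_{s}"] = shoulder + (L + 0.10) * down
    return out


def simulate_motion(config: SimulationConfig, subject: SubjectParams,
                    label: str, seed: int,
                    recording_id: str | None = None
                    ) -> tuple[MotionRecording, GroundTruth]:
    """Simulate one arm raise of one subject at one instructed speed.

    The same ``(config, subject, label, seed)`` always reproduces the
    recording bit for bit.
    """
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown class {label!r}")
    rng = np.random.default_rng(seed)
    L = subject.arm_length
    side = subject.dominant_side
    radius_hand = L + config.hand_offset
    dtheta = math.radians(config.delta_theta_deg)
    path = radius_hand * dtheta
    target = config.class_speeds[label] * subject.speed_multiplier
    D = path / target
    total = config.pre_hold + D + config.post_hold

    # timestamps: cumulative truncated-Gaussian intervals covering the
    # motion plus holds, padded to the minimum frame count
    est = int(math.ceil(total / config.dt_mean * 1.5)) + config.min_frames
    t = np.concatenate([[0.0], np.cumsum(_draw_intervals(rng, est, config))])
    idx = int(np.searchsorted(t, total))
    n = max(config.min_frames, idx + 1)
    while n > t.size:  # extremely unlikely; top up deterministically
        t = np.concatenate(
            [t, t[-1] + np.cumsum(_draw_intervals(rng, est, config))])
    t = t[:n]

    tau = np.clip((t - config.pre_hold) / D, 0.0, 1.0)
    theta = dtheta * _minimum_jerk(tau)

    base = _static_skeleton(side, L)
    positions = np.empty((n, len(KINECT_JOINTS), 3))
    side_sign = 1.0 if side == "right" else -1.0
    u_hat = np.array([side_sign * math.sqrt(0.5), 0.0, -math.sqrt(0.5)])
    y_hat = np.array([0.0, 1.0, 0.0])
    direction = (np.sin(theta)[:, None] * u_hat
                 - np.cos(theta)[:, None] * y_hat)     # unit ray, shape (n,3)
    # the skeleton's shoulder point elevates with the scapula as the arm
    # rises; the whole arm chain roots at the moving shoulder
    sway = config.shoulder_sway * _minimum_jerk(tau)[:, None] * y_hat
    shoulder = base[f"SHOULDER_{side.upper()}"] + sway
    radii = {"ELBOW": config.upper_arm_fraction * L, "WRIST": L,
             "HAND": radius_hand}
    for j, name in enumerate(KINECT_JOINTS):
        if name.endswith(side.upper()) and name.split("_")[0] in radii:
            r = radii[name.split("_")[0]]
            positions[:, j, :] = shoulder + r * direction
        elif name == f"SHOULDER_{side.upper()}":
            positions[:, j, :] = shoulder
        else:
            positions[:, j, :] = base[name]
    if config.position_noise_sd > 0:
        positions = positions + rng.normal(0.0, config.position_noise_sd,
                                           positions.shape)

    rid = recording_id or f"{subject.subject_id}_{label}"
    rec = MotionRecording(
        recording_id=rid,
        subject_id=subject.subject_id,
        dominant_side=side,
        joints=KINECT_JOINTS,
        timestamps=t,
        positions=positions,
        nominal_fs=config.nominal_fs,
        label=label,
    )
    truth = GroundTruth(
        recording_id=rid, subject_id=subject.subject_id, label=label,
        target_speed=target, movement_duration=D,
        total_duration=float(t[-1]), arm_length=L, n_frames=n, seed=seed,
    )
    return rec, truth


def draw_subjects(config: SimulationConfig,
                  rng: np.random.Generator) -> list[SubjectParams]:
    """Draw per-subject anthropometry and speed disposition.

    Arm lengths are Normal(mean, sd) truncated to the configured bounds by
    redrawing; a fraction of subjects matching the benchmark cohort (2 of
    27) is left-handed.
    """
    n_left = round(config.n_subjects * 2 / 27)
    left_idx = set(rng.choice(config.n_subjects, size=n_left, replace=False)
                   .tolist()) if n_left else set()
    subjects = []
    lo, hi = config.arm_length_bounds
    for i in range(config.n_subjects):
        L = float(rng.normal(config.arm_length_mean, config.arm_length_sd))
        while not lo < L < hi:
            L = float(rng.normal(config.arm_length_mean, config.arm_length_sd))
        mult = max(float(rng.normal(1.0, config.subject_speed_sd)), 0.2)
        subjects.append(SubjectParams(
            subject_id=f"S{i + 1:02d}", arm_length=L, speed_multiplier=mult,
            dominant_side="left" if i in left_idx else "right",
        ))
    return subjects


def simulate_cohort(config: SimulationConfig | None = None
                    ) -> tuple[Dataset, list[GroundTruth]]:
    """Simulate a full cohort: n_subjects x reps_per_class x 3 recordings.

    Annotations are set to the true class for both annotators (consensus
    always agrees).  Fully reproducible from ``config.seed``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    subjects = draw_subjects(config, rng)
    recordings: dict[str, MotionRecording] = {}
    annotations: list[AnnotationRecord] = []
    truths: list[GroundTruth] = []
    for subject in subjects:
        for label in CLASS_LABELS:
            for rep in range(1, config.reps_per_class + 1):
                rid = f"{subject.subject_id}_{label}_r{rep}"
                rec_seed = int(rng.integers(0, 2**31 - 1))
                rec, truth = simulate_motion(config, subject, label,
                                             seed=rec_seed, recording_id=rid)
                recordings[rid] = rec
                truths.append(truth)
                annotations.append(AnnotationRecord(
                    recording_id=rid, annotator_labels=(label, label)))
    return Dataset(recordings=recordings, annotations=annotations), truths


def jitter_statistics(config: SimulationConfig, n_intervals: int = 100_000,
                      seed: int = 0) -> dict[str, float]:
    """Sample mean/SD of the generator's frame-interval model."""
    if n_intervals < 100:
        raise ValueError("need at least 100 intervals")
    rng = np.random.default_rng(seed)
    dt = _draw_intervals(rng, n_intervals, config)
    return {"mean_dt": float(np.mean(dt)), "sd_dt": float(np.std(dt))}
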