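"""The four scalar movement features and their partial-motion variants.

For one joint of one recording:

    f1 = mean of the instantaneous velocity      [m/s]
    f2 = population SD of the velocity           [m/s]
    f3 = mean of the instantaneous acceleration  [m/s^2]
    f4 = population SD of the acceleration       [m/s^2]

SDs are population (divide by N) quantities.  N is the velocity-series
length for f1/f2 and the acceleration-series length for f3/f4.  Partial-
motion variants evaluate the same features on a prefix of the recording or
on one of ten canonical 10% windows, to ask how early in a movement the
speed class becomes predictable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import (VelocitySeries, instantaneous_acceleration,
                         instantaneous_velocity, lowpass_zero_phase)
from .motion_io import Dataset, MotionRecording

__all__ = [
    "FeatureVector",
    "MotionSlice",
    "SliceTooShortError",
    "extract_features",
    "prefix_features",
    "window_features",
    "canonical_windows",
    "feature_table",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("f1", "f2", "f3", "f4")

#: Minimum number of velocity samples in any (sliced) feature computation.
#: Two samples keep the SD defined; a fast raise at 30 Hz is only ~30
#: frames long, so a 10% window cannot be required to hold more.
_MIN_VELOCITY_SAMPLES = 2


class SliceTooShortError(ValueError):
    """A requested prefix/window leaves too few samples to form features."""


@dataclass
class FeatureVector:
    """f1-f4 for one joint of one recording (or a slice of it).

    ``f3``/``f4`` are NaN when the slice leaves fewer than two acceleration
    samples; full-motion extraction always yields all four.
    """

    recording_id: str
    joint: str
    filtered: bool
    f1: float
    f2: float
    f3: float
    f4: float
    n_velocity: int
    n_acceleration: int

    @property
    def N(self) -> int:
        """Velocity sample count (the N of f1/f2)."""
        return self.n_velocity

    def __getitem__(self, name: str) -> float:
        if name not in FEATURE_NAMES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class MotionSlice:
    """A half-open fractional window [start, end) of a motion's frames."""

    start_fraction: float
    end_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_fraction < self.end_fraction <= 1.0):
            raise ValueError(
                f"invalid slice [{self.start_fraction}, {self.end_fraction})"
            )

    def frame_bounds(self, n_frames: int) -> tuple[int, int]:
        """Map fractions to frame indices; end fraction 1 maps to n."""
        a = math.floor(self.start_fraction * n_frames)
        b = math.floor(self.end_fraction * n_frames)
        return a, b


def canonical_windows() -> list[MotionSlice]:
    """The ten sequential 10% windows [0,0.1), [0.1,0.2), ..., [0.9,1.0]."""
    return [MotionSlice(k / 10, (k + 1) / 10) for k in range(10)]


def _features_from_velocity(values: np.ndarray, T: float, recording_id: str,
                            joint: str, filtered: bool) -> FeatureVector:
    n_vel = int(values.size)
    if n_vel < _MIN_VELOCITY_SAMPLES:
        raise SliceTooShortError(
            f"{recording_id}/{joint}: {n_vel} velocity sample(s), "
            f"need >= {_MIN_VELOCITY_SAMPLES}"
        )
    acc = np.diff(values) / T
    n_acc = int(acc.size)
    if n_acc >= 2:
        f3, f4 = float(np.mean(acc)), float(np.std(acc))
    else:
        f3, f4 = math.nan, math.nan
    return FeatureVector(
        recording_id=recording_id,
        joint=joint,
        filtered=filtered,
        f1=float(np.mean(values)),
        f2=float(np.std(values)),  # population SD
        f3=f3,
        f4=f4,
        n_velocity=n_vel,
        n_acceleration=n_acc,
    )


def _velocity(rec: MotionRecording, joint: str, filtered: bool,
              timing: str, cutoff: float, filter_method: str) -> VelocitySeries:
    v = instantaneous_velocity(rec, joint, timing=timing)
    if filtered:
        v = lowpass_zero_phase(v, cutoff=cutoff, method=filter_method)
    return v


def extract_features(rec: MotionRecording, joint: str, filtered: bool = False,
                     timing: str = "nominal", cutoff: float = 6.0,
                     filter_method: str = "exact") -> FeatureVector:
    """Compute f1-f4 for one joint over the whole recording.

    f1/f2 are taken over the (optionally filtered) velocity series and
    f3/f4 over the acceleration derived from that same series.
    """
    v = _velocity(rec, joint, filtered, timing, cutoff, filter_method)
    fv = _features_from_velocity(v.values, v.sampling_interval,
                                 rec.recording_id, joint, filtered)
    if fv.n_acceleration < 2:
        raise ValueError(
            f"{rec.recording_id}: recording too short for acceleration features"
        )
    return fv


def _sliced(rec: MotionRecording, joint: str, filtered: bool,
            a: int, b: int, timing: str, cutoff: float, filter_method: str,
            refilter: bool) -> FeatureVector:
    """Features over the frame window [a, b).

    With ``refilter=False`` (default) the whole velocity series is filtered
    once and then sliced — the filter sees the full motion, so short slices
    carry no extra edge transients.  With ``refilter=True`` the raw velocity
    slice is filtered on its own.
    """
    n = rec.n_frames
    if not (0 <= a < b <= n):
        raise SliceTooShortError(f"frame window [{a}, {b}) outside 0..{n}")
    # velocity sample k spans frames k -> k+1, so frames [a, b) own samples
    # a .. b-2 of the full series
    if refilter and filtered:
        raw = instantaneous_velocity(rec, joint, timing=timing)
        seg = VelocitySeries(joint=joint, values=raw.values[a:b - 1],
                             sampling_interval=raw.sampling_interval)
        try:
            seg = lowpass_zero_phase(seg, cutoff=cutoff, method=filter_method)
        except ValueError as exc:
            raise SliceTooShortError(str(exc)) from exc
        values, T = seg.values, seg.sampling_interval
    else:
        v = _velocity(rec, joint, filtered, timing, cutoff, filter_method)
        values, T = v.values[a:b - 1], v.sampling_interval
    return _features_from_velocity(values, T, rec.recording_id, joint, filtered)


def prefix_features(rec: MotionRecording, joint: str, filtered: bool,
                    fraction: float, timing: str = "nominal",
                    cutoff: float = 6.0, filter_method: str = "exact",
                    refilter: bool = False) -> FeatureVector:
    """Features over the first ``floor(fraction * n)`` frames only.

    ``fraction=1`` reproduces :func:`extract_features` exactly.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    m = math.floor(fraction * rec.n_frames)
    return _sliced(rec, joint, filtered, 0, m, timing, cutoff,
                   filter_method, refilter)


def window_features(rec: MotionRecording, joint: str, filtered: bool,
                    slice_: MotionSlice | tuple[float, float],
                    timing: str = "nominal", cutoff: float = 6.0,
                    filter_method: str = "exact",
                    refilter: bool = False) -> FeatureVector:
    """Features over the fractional frame window ``[start, end)``."""
    if not isinstance(slice_, MotionSlice):
        slice_ = MotionSlice(*slice_)
    a, b = slice_.frame_bounds(rec.n_frames)
    return _sliced(rec, joint, filtered, a, b, timing, cutoff,
                   filter_method, refilter)


def feature_table(dataset: Dataset, joint: str, filtered: bool = False,
                  timing: str = "nominal", cutoff: float = 6.0,
                  filter_method: str = "exact",
                  slice_: MotionSlice | None = None,
                  prefix: float | None = None,
                  refilter: bool = False) -> pd.DataFrame:
    """One feature row per labeled recording of a dataset.

    Columns: recording_id, subject_id, label, joint, filtered, f1..f4, N.
    ``slice_``/``prefix`` restrict every recording to a window or prefix;
    a recording too short for the requested slice raises
    :class:`SliceTooShortError`.
    """
    if slice_ is not None and prefix is not None:
        raise ValueError("give at most one of slice_ and prefix")
    rows = []
    for rec, label in dataset.labeled_recordings():
        if slice_ is not None:
            fv = window_features(rec, joint, filtered, slice_, timing,
                                 cutoff, filter_method, refilter)
        elif prefix is not None:
            fv = prefix_features(rec, joint, filtered, prefix, timing,
                                 cutoff, filter_method, refilter)
        else:
            fv = extract_features(rec, joint, filtered, timing, cutoff,
                                  filter_method)
        rows.append({
            "recording_id": rec.recording_id,
            "subject_id": rec.subject_id,
            "label": label,
            "joint": joint,
            "filtered": filtered,
            "f1": fv.f1, "f2": fv.f2, "f3": fv.f3, "f4": fv.f4,
            "N": fv.N,
        })
    return pd.DataFrame(rows)
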