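"""On-disk formats and in-memory containers for skeletal motion recordings.

A recording is one pre-segmented arm movement: per-frame timestamps (seconds)
plus the 3D positions (meters, right-handed camera frame) of up to 20 named
skeleton joints.  Two plain-text serializations are defined: a CSV dialect
with ``#``-prefixed metadata lines followed by a ``t,<JOINT>_x,<JOINT>_y,
<JOINT>_z,...`` table, and an equivalent JSON document.  A dataset directory
holds ``recordings/*.csv`` plus an ``annotations.csv`` with the two
annotators' speed labels and their consensus.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARM_JOINTS",
    "KINECT_JOINTS",
    "CLASS_LABELS",
    "DISCARDED",
    "UNLABELED",
    "ParseError",
    "MotionRecording",
    "AnnotationRecord",
    "Dataset",
    "consensus_label",
    "timing_summary",
    "read_recording",
    "write_recording",
    "read_dataset",
    "write_dataset",
]

#: The three speed classes, ordered slow -> fast.
CLASS_LABELS = ("slow", "normal", "fast")
DISCARDED = "discarded"
UNLABELED = "unlabeled"

#: Side-less names of the four arm joints every recording must resolve.
ARM_JOINTS = ("SHOULDER", "ELBOW", "WRIST", "HAND")

#: The 20 joints of the first-generation Kinect skeleton.
KINECT_JOINTS = (
    "HIP_CENTER", "SPINE", "SHOULDER_CENTER", "HEAD",
    "SHOULDER_LEFT", "ELBOW_LEFT", "WRIST_LEFT", "HAND_LEFT",
    "SHOULDER_RIGHT", "ELBOW_RIGHT", "WRIST_RIGHT", "HAND_RIGHT",
    "HIP_LEFT", "KNEE_LEFT", "ANKLE_LEFT", "FOOT_LEFT",
    "HIP_RIGHT", "KNEE_RIGHT", "ANKLE_RIGHT", "FOOT_RIGHT",
)


class ParseError(ValueError):
    """A recording or annotation file violates the documented dialect."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParseError(msg)


@dataclass
class MotionRecording:
    """One timestamped movement of one subject.

    Parameters
    ----------
    recording_id, subject_id : str
        Identifiers; the recording id doubles as the file stem on disk.
    dominant_side : {"left", "right"}
        Side whose arm joints the side-less names in :data:`ARM_JOINTS`
        resolve to.
    joints : sequence of str
        Joint names, one per column triplet; order defines the position axis.
    timestamps : ndarray, shape (n,)
        Strictly increasing frame times in seconds.
    positions : ndarray, shape (n, J, 3)
        Joint positions in meters, camera/world coordinates.
    nominal_fs : float
        Nominal sampling rate in Hz (the depth camera advertises 30).
    label : str
        Speed class if known, else ``"unlabeled"``.
    synthetic_timing : bool
        True when timestamps were reconstructed from ``nominal_fs`` rather
        than recorded by the sensor.
    """

    recording_id: str
    subject_id: str
    dominant_side: str
    joints: Sequence[str]
    timestamps: np.ndarray
    positions: np.ndarray
    nominal_fs: float = 30.0
    label: str = UNLABELED
    synthetic_timing: bool = False

    def __post_init__(self) -> None:
        self.joints = tuple(self.joints)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.dominant_side not in ("left", "right"):
            raise ValueError(f"dominant_side must be left|right, got {self.dominant_side!r}")
        if self.label not in CLASS_LABELS + (UNLABELED,):
            raise ValueError(f"unknown label {self.label!r}")
        n = self.timestamps.shape[0]
        if n < 2:
            raise ValueError(f"recording {self.recording_id!r}: need at least 2 frames, got {n}")
        if self.positions.shape != (n, len(self.joints), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{n} frames x {len(self.joints)} joints x 3"
            )
        if len(set(self.joints)) != len(self.joints):
            raise ValueError("joint names must be unique")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps not strictly increasing")
        if not np.all(np.isfinite(self.timestamps)):
            raise ValueError("non-finite timestamp")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite position coordinate")
        if self.nominal_fs <= 0:
            raise ValueError("nominal_fs must be positive")
        # the four dominant-side arm joints must be resolvable
        for name in ARM_JOINTS:
            self.joint_index(name)

    @property
    def n_frames(self) -> int:
        return int(self.timestamps.shape[0])

    def joint_index(self, joint: str) -> int:
        """Resolve a joint name to its column index.

        Side-less arm-joint names (``"HAND"``) resolve to the dominant side
        (``"HAND_RIGHT"`` for a right-handed subject).
        """
        if joint in self.joints:
            return self.joints.index(joint)
        sided = f"{joint}_{self.dominant_side.upper()}"
        if sided in self.joints:
            return self.joints.index(sided)
        raise KeyError(f"joint {joint!r} not present in recording {self.recording_id!r}")

    def joint_positions(self, joint: str) -> np.ndarray:
        """Positions of one joint, shape (n, 3)."""
        return self.positions[:, self.joint_index(joint), :]


@dataclass
class AnnotationRecord:
    """Two annotators' speed labels for one recording plus their consensus."""

    recording_id: str
    annotator_labels: Sequence[str]
    consensus: str = field(default="")

    def __post_init__(self) -> None:
        self.annotator_labels = tuple(self.annotator_labels)
        expected = consensus_label(self.annotator_labels)
        if not self.consensus:
            self.consensus = expected
        elif self.consensus != expected:
            raise ValueError(
                f"annotation {self.recording_id!r}: consensus {self.consensus!r} "
                f"inconsistent with labels {self.annotator_labels!r}"
            )


def consensus_label(labels: Sequence[str]) -> str:
    """Consensus of exactly two annotators.

    Agreement yields the common label; disagreement yields ``"discarded"``
    (in the original protocol the subject then repeated the movement).
    """
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 annotator labels, got {len(labels)}")
    a, b = labels
    for lab in (a, b):
        if lab not in CLASS_LABELS:
            raise ValueError(f"unknown class label {lab!r}")
    return a if a == b else DISCARDED


@dataclass
class Dataset:
    """A collection of recordings plus their annotations."""

    recordings: dict[str, MotionRecording]
    annotations: list[AnnotationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ann in self.annotations:
            if ann.consensus != DISCARDED and ann.recording_id not in self.recordings:
                raise ValueError(
                    f"annotation references unknown recording {ann.recording_id!r}"
                )

    def __len__(self) -> int:
        return len(self.recordings)

    @property
    def subjects(self) -> list[str]:
        return sorted({rec.subject_id for rec in self.recordings.values()})

    def label_of(self, recording_id: str) -> str:
        """Consensus label if annotated, else the recording's own label."""
        for ann in self.annotations:
            if ann.recording_id == recording_id:
                return ann.consensus
        return self.recordings[recording_id].label

    def labeled_recordings(self) -> Iterator[tuple[MotionRecording, str]]:
        """Yield (recording, class label) pairs, skipping discarded/unlabeled."""
        ann_map = {a.recording_id: a.consensus for a in self.annotations}
        for rid in sorted(self.recordings):
            rec = self.recordings[rid]
            label = ann_map.get(rid, rec.label)
            if label in CLASS_LABELS:
                yield rec, label


def timing_summary(rec: MotionRecording) -> dict[str, float | None]:
    """Summarize the sampling-interval statistics of a recording.

    Returns ``mean_dt``/``sd_dt`` (mean and population SD of consecutive
    timestamp differences, seconds) and the implied sampling rates
    ``fs_mean = 1/mean_dt``, ``fs_min = 1/(mean_dt + sd_dt)`` and
    ``fs_max = 1/(mean_dt - sd_dt)``.  ``fs_max`` is ``None`` when
    ``sd_dt >= mean_dt``.
    """
    if rec.n_frames < 3:
        raise ValueError("timing_summary needs at least 3 frames")
    dt = np.diff(rec.timestamps)
    mean_dt = float(np.mean(dt))
    sd_dt = float(np.std(dt))  # population SD, matching the Gaussian fit
    fs_max: float | None
    if sd_dt >= mean_dt:
        fs_max = None
    else:
        fs_max = 1.0 / (mean_dt - sd_dt)
    return {
        "mean_dt": mean_dt,
        "sd_dt": sd_dt,
        "fs_mean": 1.0 / mean_dt,
        "fs_min": 1.0 / (mean_dt + sd_dt),
        "fs_max": fs_max,
    }


# ---------------------------------------------------------------------------
# serialization

_META_KEYS = ("recording_id", "subject_id", "dominant_side", "nominal_fs",
              "label", "synthetic_timing")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_recording(path: str | Path, format: str | None = None) -> MotionRecording:
    """Read and validate a recording from CSV or JSON.

    When the CSV has no ``t`` column, timestamps are synthesized on the
    nominal grid ``k / nominal_fs`` and the recording is flagged as having
    synthetic timing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "json":
        return _read_json(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_json(path: Path) -> MotionRecording:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        meta = doc.get("meta", {})
        return MotionRecording(
            recording_id=meta.get("recording_id", path.stem),
            subject_id=meta.get("subject_id", "unknown"),
            dominant_side=meta.get("dominant_side", "right"),
            joints=doc["joints"],
            timestamps=np.asarray(doc["t"], dtype=float),
            positions=np.asarray(doc["pos"], dtype=float),
            nominal_fs=float(meta.get("nominal_fs", 30.0)),
            label=meta.get("label", UNLABELED),
            synthetic_timing=bool(meta.get("synthetic_timing", False)),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _read_csv(path: Path) -> MotionRecording:
    meta: dict[str, str] = {}
    header_line = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                header_line += 1
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
            else:
                break
    try:
        table = pd.read_csv(path, skiprows=header_line)
    except Exception as exc:  # malformed table
        raise ParseError(f"{path}: malformed CSV table ({exc})") from exc
    _require(len(table.columns) >= 3, f"{path}: too few columns")

    cols = list(table.columns)
    has_t = cols[0] == "t"
    coord_cols = cols[1:] if has_t else cols
    _require(len(coord_cols) % 3 == 0,
             f"{path}: coordinate columns not a multiple of 3 ({len(coord_cols)})")
    joints = []
    for j in range(0, len(coord_cols), 3):
        trip = coord_cols[j:j + 3]
        names = {c.rsplit("_", 1)[0] for c in trip}
        axes = [c.rsplit("_", 1)[1] if "_" in c else "?" for c in trip]
        _require(len(names) == 1 and axes == ["x", "y", "z"],
                 f"{path}: malformed header triplet {trip}")
        joints.append(trip[0].rsplit("_", 1)[0])

    values = table.to_numpy(dtype=float)
    n = values.shape[0]
    _require(n >= 2, f"{path}: need at least 2 frames, got {n}")
    nominal_fs = float(meta.get("nominal_fs", 30.0))
    if has_t:
        timestamps = values[:, 0]
        pos = values[:, 1:]
        synthetic = meta.get("synthetic_timing", "false").lower() == "true"
    else:
        timestamps = np.arange(n) / nominal_fs
        pos = values
        synthetic = True

    bad = np.where(~np.isfinite(pos))
    if bad[0].size:
        r, c = int(bad[0][0]), int(bad[1][0])
        raise ParseError(
            f"{path}: non-finite coordinate at data row {r + 1}, "
            f"field {coord_cols[c]!r}"
        )
    d = np.diff(timestamps)
    if not np.all(d > 0):
        k = int(np.argmin(d > 0))
        raise ParseError(
            f"{path}: timestamps not strictly increasing at data row {k + 2}"
        )
    try:
        return MotionRecording(
            recording_id=meta.get("recording_id", path.stem),
            subject_id=meta.get("subject_id", "unknown"),
            dominant_side=meta.get("dominant_side", "right"),
            joints=joints,
            timestamps=timestamps,
            positions=pos.reshape(n, len(joints), 3),
            nominal_fs=nominal_fs,
            label=meta.get("label", UNLABELED),
            synthetic_timing=synthetic,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_recording(rec: MotionRecording, path: str | Path,
                    format: str | None = None) -> None:
    """Write a recording; ``read_recording`` round-trips it to <=1e-9."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = {
            "format": "kinespeed-recording",
            "meta": {
                "recording_id": rec.recording_id,
                "subject_id": rec.subject_id,
                "dominant_side": rec.dominant_side,
                "nominal_fs": rec.nominal_fs,
                "label": rec.label,
                "synthetic_timing": rec.synthetic_timing,
            },
            "joints": list(rec.joints),
            "t": rec.timestamps.tolist(),
            "pos": rec.positions.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
        return
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")
    header = ["t"]
    for joint in rec.joints:
        header += [f"{joint}_x", f"{joint}_y", f"{joint}_z"]
    flat = np.column_stack([rec.timestamps,
                            rec.positions.reshape(rec.n_frames, -1)])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# kinespeed-recording v1\n")
        fh.write(f"# recording_id={rec.recording_id}\n")
        fh.write(f"# subject_id={rec.subject_id}\n")
        fh.write(f"# dominant_side={rec.dominant_side}\n")
        fh.write(f"# nominal_fs={rec.nominal_fs:.17g}\n")
        fh.write(f"# label={rec.label}\n")
        fh.write(f"# synthetic_timing={'true' if rec.synthetic_timing else 'false'}\n")
        fh.write(",".join(header) + "\n")
        for row in flat:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def write_dataset(dataset: Dataset, directory: str | Path) -> None:
    """Write a dataset as ``recordings/*.csv`` plus ``annotations.csv``."""
    directory = Path(directory)
    rec_dir = directory / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for rid, rec in dataset.recordings.items():
        write_recording(rec, rec_dir / f"{rid}.csv")
    rows = [
        {
            "recording_id": a.recording_id,
            "annotator1": a.annotator_labels[0],
            "annotator2": a.annotator_labels[1],
            "consensus": a.consensus,
        }
        for a in dataset.annotations
    ]
    pd.DataFrame(rows, columns=["recording_id", "annotator1", "annotator2",
                                "consensus"]).to_csv(
        directory / "annotations.csv", index=False)


def read_dataset(directory: str | Path) -> Dataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    rec_dir = directory / "recordings"
    if not rec_dir.is_dir():
        raise FileNotFoundError(f"dataset not found: {directory}")
    recordings = {}
    for path in sorted(rec_dir.glob("*.csv")) + sorted(rec_dir.glob("*.json")):
        rec = read_recording(path)
        recordings[rec.recording_id] = rec
    annotations = []
    ann_path = directory / "annotations.csv"
    if ann_path.exists():
        table = pd.read_csv(ann_path)
        for _, row in table.iterrows():
            annotations.append(AnnotationRecord(
                recording_id=str(row["recording_id"]),
                annotator_labels=(str(row["annotator1"]), str(row["annotator2"])),
                consensus=str(row["consensus"]) if "consensus" in row else "",
            ))
    return Dataset(recordings=recordings, annotations=annotations)
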