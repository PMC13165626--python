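"""Skeleton data model and pose-sequence file formats.

The engine consumes per-frame named 3D joints — the typical output shape of
monocular 3D pose estimators built on the Human3.6M 17-joint skeleton. Two
on-disk encodings are supported:

* a JSON document with sequence metadata and one object per frame, and
* a long-format CSV (``frame,joint,x,y,z``) with metadata supplied
  separately (sidecar values or CLI flags).

Both parse to the same validated :class:`PoseSequence`; parsing never drops
or reorders frames, and unknown joint names are rejected rather than
silently ignored.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import PoseValidationError

#: Closed 17-joint vocabulary (Human3.6M-style skeleton).
JOINT_NAMES: tuple[str, ...] = (
    "pelvis", "spine", "thorax", "neck", "head",
    "l_shoulder", "r_shoulder", "l_elbow", "r_elbow", "l_wrist", "r_wrist",
    "l_hip", "r_hip", "l_knee", "r_knee", "l_ankle", "r_ankle",
)
_JOINT_SET = frozenset(JOINT_NAMES)

#: Valid task labels (five cabinet-operation tasks).
TASK_LABELS: tuple[str, ...] = (
    "sliding_door", "mid_drawer", "low_drawer",
    "mid_hinged_door", "low_hinged_door",
)

GROUP_LABELS: tuple[str, ...] = ("experimental", "simulation")


class PoseFrame(BaseModel):
    """One frame of named 3D joints; absent joints are explicitly missing."""

    model_config = ConfigDict(frozen=True)

    index: int
    joints: Mapping[str, tuple[float, float, float]]

    @field_validator("index")
    @classmethod
    def _index_nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError(f"frame index must be non-negative, got {v}")
        return v

    @field_validator("joints")
    @classmethod
    def _check_joints(cls, joints):
        for name, xyz in joints.items():
            if name not in _JOINT_SET:
                raise ValueError(f"unknown joint name '{name}'")
            if len(xyz) != 3:
                raise ValueError(f"joint '{name}' must have 3 coordinates")
            if not all(math.isfinite(c) for c in xyz):
                raise ValueError(f"joint '{name}' has non-finite coordinates")
        return {k: tuple(float(c) for c in v) for k, v in joints.items()}

    def joint(self, name: str) -> np.ndarray | None:
        """Return the joint position as an array, or None if missing."""
        xyz = self.joints.get(name)
        return None if xyz is None else np.asarray(xyz, dtype=float)

    def has(self, *names: str) -> bool:
        return all(n in self.joints for n in names)


class PoseSequence(BaseModel):
    """Ordered frames with frame rate, task/group metadata and a vertical axis."""

    model_config = ConfigDict(frozen=True)

    frames: tuple[PoseFrame, ...]
    fps: float = 30.0
    task: str | None = None
    group: str | None = None
    up_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)

    @field_validator("fps")
    @classmethod
    def _fps_positive(cls, v: float) -> float:
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"fps must be positive and finite, got {v}")
        return v

    @field_validator("task")
    @classmethod
    def _task_known(cls, v):
        if v is not None and v not in TASK_LABELS:
            raise ValueError(f"unknown task '{v}'; valid: {', '.join(TASK_LABELS)}")
        return v

    @field_validator("group")
    @classmethod
    def _group_known(cls, v):
        if v is not None and v not in GROUP_LABELS:
            raise ValueError(f"unknown group '{v}'; valid: {', '.join(GROUP_LABELS)}")
        return v

    @field_validator("up_axis")
    @classmethod
    def _unit_up(cls, v):
        norm = math.sqrt(sum(c * c for c in v))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"up_axis must have unit norm, got |{v}| = {norm}")
        return tuple(float(c) for c in v)

    @model_validator(mode="after")
    def _indices_increasing(self):
        idx = [f.index for f in self.frames]
        for a, b in zip(idx, idx[1:]):
            if b <= a:
                raise ValueError(
                    f"frame indices must be strictly increasing; got {a} then {b}"
                )
        return self

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _wrap(exc: Exception, path: Path) -> PoseValidationError:
    return PoseValidationError(f"{path}: {exc}")


def read_pose_json(path: str | Path) -> PoseSequence:
    """Read a pose sequence from the JSON format.

    Missing joints (``null`` entries or absent keys) are preserved as
    missing; coordinates are taken verbatim with no unit conversion.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PoseValidationError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(doc, dict) or "frames" not in doc:
        raise PoseValidationError(f"{path}: missing top-level 'frames' field")
    frames = []
    for i, fr in enumerate(doc["frames"]):
        if not isinstance(fr, dict) or "index" not in fr or "joints" not in fr:
            raise PoseValidationError(
                f"{path}: frame entry {i} lacks 'index'/'joints' fields"
            )
        joints = {k: v for k, v in fr["joints"].items() if v is not None}
        try:
            frames.append(PoseFrame(index=fr["index"], joints=joints))
        except ValueError as exc:
            raise _wrap(exc, path) from exc
    meta = {k: doc[k] for k in ("fps", "task", "group", "up_axis") if k in doc}
    if "up_axis" in meta:
        meta["up_axis"] = tuple(meta["up_axis"])
    try:
        return PoseSequence(frames=tuple(frames), **meta)
    except ValueError as exc:
        raise _wrap(exc, path) from exc


def write_pose_json(seq: PoseSequence, path: str | Path) -> None:
    """Write the canonical JSON encoding (sorted joint keys, stable layout)."""
    doc = {
        "fps": seq.fps,
        "task": seq.task,
        "group": seq.group,
        "up_axis": list(seq.up_axis),
        "frames": [
            {
                "index": f.index,
                "joints": {name: list(f.joints[name]) for name in sorted(f.joints)},
            }
            for f in seq.frames
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_pose_csv(
    path: str | Path,
    *,
    fps: float = 30.0,
    task: str | None = None,
    group: str | None = None,
    up_axis: Sequence[float] = (0.0, 1.0, 0.0),
) -> PoseSequence:
    """Read a long-format CSV (``frame,joint,x,y,z``) pose sequence.

    Metadata is not part of the CSV payload; pass it via keyword arguments
    (the CLI forwards its flags here).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PoseValidationError(f"{path}: empty file") from None
        expected = ["frame", "joint", "x", "y", "z"]
        if [h.strip() for h in header] != expected:
            raise PoseValidationError(
                f"{path}: header must be {','.join(expected)}; got {','.join(header)}"
            )
        per_frame: dict[int, dict[str, tuple[float, float, float]]] = {}
        order: list[int] = []
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise PoseValidationError(f"{path}: row {row_no}: expected 5 columns")
            try:
                idx = int(row[0])
                xyz = (float(row[2]), float(row[3]), float(row[4]))
            except ValueError as exc:
                raise PoseValidationError(
                    f"{path}: row {row_no}: non-numeric value ({exc})"
                ) from exc
            if idx not in per_frame:
                per_frame[idx] = {}
                order.append(idx)
            joint = row[1].strip()
            if joint in per_frame[idx]:
                raise PoseValidationError(
                    f"{path}: row {row_no}: duplicate joint '{joint}' in frame {idx}"
                )
            per_frame[idx][joint] = xyz
    if not per_frame:
        raise PoseValidationError(f"{path}: empty sequence (no data rows)")
    if order != sorted(order):
        raise PoseValidationError(f"{path}: frame indices not strictly increasing")
    try:
        frames = tuple(
            PoseFrame(index=i, joints=per_frame[i]) for i in order
        )
        return PoseSequence(
            frames=frames, fps=fps, task=task, group=group,
            up_axis=tuple(up_axis),
        )
    except ValueError as exc:
        raise _wrap(exc, path) from exc


def write_pose_csv(seq: PoseSequence, path: str | Path) -> None:
    """Write the long-format CSV encoding (joints sorted within each frame)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "joint", "x", "y", "z"])
        for f in seq.frames:
            for name in sorted(f.joints):
                x, y, z = f.joints[name]
                writer.writerow([f.index, name, repr(x), repr(y), repr(z)])


def write_risk_csv(traj, path: str | Path) -> None:
    """Write a risk trajectory as CSV (``frame,s_raw,s_smooth,level,category,phase``).

    Scores are formatted with 6 decimal places so repeated runs produce
    byte-identical files; invalid frames emit empty level/category cells.
    """
    frames = list(traj)
    if not frames:
        raise PoseValidationError("cannot write an empty trajectory")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "s_raw", "s_smooth", "level", "category", "phase"])
        for f in frames:
            writer.writerow([
                f.frame_index,
                f"{f.s_raw:.6f}",
                f"{f.s_smooth:.6f}",
                "" if f.level is None else f.level,
                "" if f.category is None else f.category,
                f.phase,
            ])


def read_risk_csv(path: str | Path) -> list[dict]:
    """Read a risk CSV back into a list of row dicts (numeric fields parsed)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        rows = []
        for row in reader:
            rows.append({
                "frame": int(row["frame"]),
                "s_raw": float(row["s_raw"]),
                "s_smooth": float(row["s_smooth"]),
                "level": int(row["level"]) if row["level"] else None,
                "category": row["category"] or None,
                "phase": row["phase"],
            })
    if not rows:
        raise PoseValidationError(f"{path}: empty trajectory file")
    return rows


def interpolate_gaps(seq: PoseSequence, max_gap: int = 5) -> PoseSequence:
    """Linearly interpolate missing joints across gaps of at most ``max_gap`` frames.

    Off by default in the pipeline: it fabricates coordinates, so it must be
    requested explicitly. A joint missing at the sequence boundary, or across
    a gap longer than ``max_gap``, stays missing.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    frames = list(seq.frames)
    n = len(frames)
    new_joints: list[dict[str, tuple[float, float, float]]] = [
        dict(f.joints) for f in frames
    ]
    for name in JOINT_NAMES:
        present = [i for i, f in enumerate(frames) if name in f.joints]
        for a, b in zip(present, present[1:]):
            gap = b - a - 1
            if 0 < gap <= max_gap:
                pa = np.asarray(frames[a].joints[name])
                pb = np.asarray(frames[b].joints[name])
                for k in range(1, gap + 1):
                    t = k / (gap + 1)
                    new_joints[a + k][name] = tuple((1 - t) * pa + t * pb)
    rebuilt = tuple(
        PoseFrame(index=f.index, joints=j) for f, j in zip(frames, new_joints)
    )
    return seq.model_copy(update={"frames": rebuilt})
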