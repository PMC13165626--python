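"""Joint-angle and reach-distance computation from 3D keypoints.

All angles are plain vector angles, ``arccos`` of the normalised dot
product, so they are invariant under global translation, rotation (with a
co-rotated vertical axis) and uniform positive scaling of the coordinates.

Conventions
-----------
shoulder
    Angle between the neck→shoulder and shoulder→elbow direction vectors.
elbow
    *Vector* convention: angle between shoulder→elbow and elbow→wrist, so a
    straight arm measures 0°. The anatomical interior angle (straight arm =
    180°) is its supplement; :func:`elbow_anatomical` exposes it because
    ergonomic membership tables are usually stated in that convention.
trunk
    *Deviation* convention: angle between the neck→mid-hip torso vector and
    the negated vertical axis, so an upright seated trunk measures 0°. The
    interior trunk/hip convention (upright = 180°) is the supplement.
reach
    Euclidean wrist↔mid-hip distance, optionally normalised by arm length
    (upper arm + forearm) to remove body-scale effects.

A frame lacking a joint required by one angle yields an invalid (NaN) entry
for that angle only; other angles of the same frame are still computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, MissingJointError
from .pose import PoseFrame, PoseSequence

#: Minimum vector norm (input units) below which geometry is degenerate.
DEFAULT_EPSILON = 1e-9

Side = str  # "left" | "right"


def _side_prefix(side: Side) -> str:
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return side[0]


@dataclass(frozen=True)
class JointAngleSet:
    """Per-frame biomechanical angles (degrees) and reach distance.

    Invalid entries are NaN; ``valid_*`` properties report validity.
    ``trunk_rotation`` is an optional extra channel (degrees of axial
    twist) that some rule bases reference; it is never computed from the
    skeleton here and defaults to absent.
    """

    frame_index: int
    theta_shoulder: float = math.nan
    theta_elbow: float = math.nan  # vector convention (straight arm = 0)
    theta_trunk: float = math.nan  # deviation from vertical (upright = 0)
    reach: float = math.nan
    trunk_rotation: float | None = None

    @property
    def theta_elbow_anatomical(self) -> float:
        """Interior elbow angle (straight arm = 180°)."""
        return 180.0 - self.theta_elbow

    @property
    def theta_trunk_interior(self) -> float:
        """Interior trunk/hip angle (upright = 180°)."""
        return 180.0 - self.theta_trunk

    @property
    def valid_shoulder(self) -> bool:
        return math.isfinite(self.theta_shoulder)

    @property
    def valid_elbow(self) -> bool:
        return math.isfinite(self.theta_elbow)

    @property
    def valid_trunk(self) -> bool:
        return math.isfinite(self.theta_trunk)

    @property
    def valid_reach(self) -> bool:
        return math.isfinite(self.reach)


def angle_between(v1, v2, *, epsilon: float = DEFAULT_EPSILON) -> float:
    """Angle in degrees between two 3-vectors, in [0, 180].

    The cosine is clamped to [-1, 1] before ``arccos`` so near-collinear
    inputs can never raise a domain error.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = float(np.linalg.norm(v1))
    n2 = float(np.linalg.norm(v2))
    if n1 <= epsilon:
        raise DegenerateGeometryError(f"first vector has near-zero norm {n1:g}")
    if n2 <= epsilon:
        raise DegenerateGeometryError(f"second vector has near-zero norm {n2:g}")
    cosang = float(np.dot(v1, v2)) / (n1 * n2)
    cosang = min(1.0, max(-1.0, cosang))
    return math.degrees(math.acos(cosang))


def _require(frame: PoseFrame, name: str) -> np.ndarray:
    p = frame.joint(name)
    if p is None:
        raise MissingJointError(name, frame.index)
    return p


def _mid_hip(frame: PoseFrame) -> np.ndarray:
    """Midpoint of the hips; falls back to the pelvis root if a hip is missing."""
    lh, rh = frame.joint("l_hip"), frame.joint("r_hip")
    if lh is not None and rh is not None:
        return 0.5 * (lh + rh)
    pelvis = frame.joint("pelvis")
    if pelvis is None:
        raise MissingJointError("l_hip/r_hip (or pelvis)", frame.index)
    return pelvis


def shoulder_angle(frame: PoseFrame, side: Side = "right",
                   *, epsilon: float = DEFAULT_EPSILON) -> float:
    """Angle between neck→shoulder and shoulder→elbow (degrees)."""
    p = _side_prefix(side)
    n = _require(frame, "neck")
    s = _require(frame, f"{p}_shoulder")
    e = _require(frame, f"{p}_elbow")
    return angle_between(s - n, e - s, epsilon=epsilon)


def elbow_angle(frame: PoseFrame, side: Side = "right",
                *, epsilon: float = DEFAULT_EPSILON) -> float:
    """Angle between shoulder→elbow and elbow→wrist (vector convention)."""
    p = _side_prefix(side)
    s = _require(frame, f"{p}_shoulder")
    e = _require(frame, f"{p}_elbow")
    w = _require(frame, f"{p}_wrist")
    return angle_between(e - s, w - e, epsilon=epsilon)


def elbow_anatomical(frame: PoseFrame, side: Side = "right",
                     *, epsilon: float = DEFAULT_EPSILON) -> float:
    """Interior elbow angle (straight arm = 180°)."""
    return 180.0 - elbow_angle(frame, side, epsilon=epsilon)


def trunk_angle(frame: PoseFrame, up_axis=(0.0, 1.0, 0.0),
                *, epsilon: float = DEFAULT_EPSILON) -> float:
    """Deviation of the torso from vertical (degrees; upright = 0°)."""
    n = _require(frame, "neck")
    h = _mid_hip(frame)
    up = np.asarray(up_axis, dtype=float)
    return angle_between(h - n, -up, epsilon=epsilon)


def reach_distance(frame: PoseFrame, side: Side = "right",
                   *, normalize: bool = False,
                   epsilon: float = DEFAULT_EPSILON) -> float:
    """Euclidean wrist↔mid-hip distance (input units).

    With ``normalize=True`` the distance is divided by the arm length
    |shoulder→elbow| + |elbow→wrist| of the same side.
    """
    p = _side_prefix(side)
    w = _require(frame, f"{p}_wrist")
    h = _mid_hip(frame)
    d = float(np.linalg.norm(w - h))
    if not normalize:
        return d
    s = _require(frame, f"{p}_shoulder")
    e = _require(frame, f"{p}_elbow")
    arm = float(np.linalg.norm(e - s)) + float(np.linalg.norm(w - e))
    if arm <= epsilon:
        raise DegenerateGeometryError("arm length is near zero")
    return d / arm


def frame_angles(frame: PoseFrame, side: Side = "right",
                 up_axis=(0.0, 1.0, 0.0), *,
                 epsilon: float = DEFAULT_EPSILON) -> JointAngleSet:
    """All angles of one frame; missing/degenerate entries become NaN."""
    vals: dict[str, float] = {}
    for key, fn in (
        ("theta_shoulder", lambda: shoulder_angle(frame, side, epsilon=epsilon)),
        ("theta_elbow", lambda: elbow_angle(frame, side, epsilon=epsilon)),
        ("theta_trunk", lambda: trunk_angle(frame, up_axis, epsilon=epsilon)),
        ("reach", lambda: reach_distance(frame, side, epsilon=epsilon)),
    ):
        try:
            vals[key] = fn()
        except (MissingJointError, DegenerateGeometryError):
            vals[key] = math.nan
    return JointAngleSet(frame_index=frame.index, **vals)


def sequence_angles(seq: PoseSequence, side: Side = "right",
                    *, epsilon: float = DEFAULT_EPSILON) -> list[JointAngleSet]:
    """One :class:`JointAngleSet` per frame, order and count preserved.

    Frames that fail a precondition yield invalid (NaN) entries for the
    affected angles; they are never dropped.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    return [
        frame_angles(f, side, seq.up_axis, epsilon=epsilon) for f in seq.frames
    ]


def angles_to_frame_rows(angles: list[JointAngleSet]) -> list[dict]:
    """Rows for the angle CSV export (``frame,theta_shoulder,...,valid_flags``)."""
    rows = []
    for a in angles:
        flags = "".join(
            "SETR"[i] if ok else "-"
            for i, ok in enumerate(
                (a.valid_shoulder, a.valid_elbow, a.valid_trunk, a.valid_reach)
            )
        )
        rows.append({
            "frame": a.frame_index,
            "theta_shoulder": a.theta_shoulder,
            "theta_elbow": a.theta_elbow,
            "theta_trunk": a.theta_trunk,
            "reach": a.reach,
            "valid_flags": flags,
        })
    return rows
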