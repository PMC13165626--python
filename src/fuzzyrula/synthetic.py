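"""Seeded synthetic seated-reach motion for the five cabinet tasks.

Real recordings of wheelchair users operating cabinets are not shipped with
the package, so an explicit generator stands in for them: each task is a
three-phase reach (approach → execution → withdrawal) in which the shoulder,
elbow and trunk angles ramp from a neutral seated posture to a task-specific
plateau along smooth cosine transitions, hold the plateau during execution,
and return. A per-sequence subject offset (Gaussian, one draw per angle)
emulates inter-subject variability; i.i.d. Gaussian frame noise emulates
pose-estimator jitter.

Profile targets are stated in the conventions ergonomic envelopes are
usually printed in — raw shoulder angle, *interior* (anatomical) elbow
angle, *interior* trunk angle — and converted internally to the vector /
deviation conventions the kinematics layer produces.

:func:`angles_to_pose` is the constructive inverse of the angle
definitions: it places the right-arm chain and torso in a sagittal plane so
that :func:`fuzzyrula.kinematics.sequence_angles` recovers the generated
series to within numerical round-off, and fills the remaining skeleton
joints with a static seated template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ConstructionError
from .kinematics import JointAngleSet
from .pose import PoseFrame, PoseSequence, TASK_LABELS

__all__ = [
    "TaskProfile", "AngleSeries", "SkeletonTemplate",
    "generate_angle_series", "angles_to_pose", "default_profiles",
    "generate_sequence",
]


@dataclass(frozen=True)
class TaskProfile:
    """Parameterization of one cabinet task.

    Plateau targets and neutral posture are given as
    ``(shoulder_raw, elbow_interior, trunk_interior)`` in degrees.
    ``variability_sd`` are per-sequence subject-offset standard deviations
    for the three angles; ``noise_sd`` is the per-frame observation noise.
    """

    task: str
    plateau: tuple[float, float, float]
    neutral: tuple[float, float, float] = (170.0, 160.0, 177.0)
    variability_sd: tuple[float, float, float] = (3.0, 3.0, 2.0)
    noise_sd: float = 2.0
    n_frames: int = 150
    fps: float = 30.0
    boundaries: tuple[int, int] = (30, 120)

    def __post_init__(self):
        for name, triple in (("plateau", self.plateau), ("neutral", self.neutral)):
            for v in triple:
                if not (0.0 < v < 180.0):
                    raise ConfigError(
                        f"profile '{self.task}': {name} angle {v} outside (0, 180)"
                    )
        if any(sd < 0 for sd in self.variability_sd) or self.noise_sd < 0:
            raise ConfigError(f"profile '{self.task}': negative noise SD")
        b1, b2 = self.boundaries
        if not (0 < b1 < b2 <= self.n_frames):
            raise ConfigError(
                f"profile '{self.task}': boundaries {self.boundaries} "
                f"invalid for {self.n_frames} frames"
            )
        if self.fps <= 0:
            raise ConfigError(f"profile '{self.task}': fps must be positive")


@dataclass(frozen=True)
class AngleSeries:
    """Generated per-frame angles, stored in the kinematics conventions.

    ``theta_shoulder`` is the raw neck→shoulder/shoulder→elbow angle,
    ``theta_elbow`` the vector convention (straight arm = 0°) and
    ``theta_trunk`` the deviation from vertical (upright = 0°).
    """

    task: str
    fps: float
    boundaries: tuple[int, int]
    theta_shoulder: np.ndarray
    theta_elbow: np.ndarray
    theta_trunk: np.ndarray
    subject_offsets: tuple[float, float, float]

    @property
    def n_frames(self) -> int:
        return self.theta_shoulder.size

    @property
    def theta_elbow_anatomical(self) -> np.ndarray:
        return 180.0 - self.theta_elbow

    @property
    def theta_trunk_interior(self) -> np.ndarray:
        return 180.0 - self.theta_trunk

    def to_angle_sets(self) -> list[JointAngleSet]:
        return [
            JointAngleSet(
                frame_index=i,
                theta_shoulder=float(self.theta_shoulder[i]),
                theta_elbow=float(self.theta_elbow[i]),
                theta_trunk=float(self.theta_trunk[i]),
            )
            for i in range(self.n_frames)
        ]


def _phase_ramp(n_frames: int, boundaries: tuple[int, int]) -> np.ndarray:
    """Activation 0→1→0: cosine rise over the approach, hold, cosine fall."""
    b1, b2 = boundaries
    t = np.arange(n_frames, dtype=float)
    r = np.ones(n_frames)
    rise = t < b1
    r[rise] = 0.5 * (1.0 - np.cos(np.pi * t[rise] / b1))
    fall = t >= b2
    if n_frames > b2:
        u = (t[fall] - b2 + 1.0) / (n_frames - b2)
        r[fall] = 0.5 * (1.0 + np.cos(np.pi * u))
    return r


def _task_stream(seed: int, task: str) -> np.random.Generator:
    """One pseudo-random stream per (seed, task), stable across task additions."""
    try:
        task_key = TASK_LABELS.index(task)
    except ValueError:
        task_key = 1000 + sum(task.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), task_key]))


def generate_angle_series(profile: TaskProfile, seed: int) -> AngleSeries:
    """Deterministic per-frame angle series for one simulated sequence."""
    rng = _task_stream(seed, profile.task)
    offsets = rng.normal(0.0, profile.variability_sd, size=3)
    noise = rng.normal(0.0, profile.noise_sd, size=(profile.n_frames, 3))
    ramp = _phase_ramp(profile.n_frames, profile.boundaries)
    series = np.empty((profile.n_frames, 3))
    for k in range(3):
        target = profile.plateau[k] + offsets[k]
        series[:, k] = profile.neutral[k] + (target - profile.neutral[k]) * ramp
    series += noise
    series = np.clip(series, 0.5, 179.5)
    return AngleSeries(
        task=profile.task,
        fps=profile.fps,
        boundaries=profile.boundaries,
        theta_shoulder=series[:, 0],
        theta_elbow=180.0 - series[:, 1],
        theta_trunk=180.0 - series[:, 2],
        subject_offsets=tuple(float(o) for o in offsets),
    )


@dataclass(frozen=True)
class SkeletonTemplate:
    """Segment lengths (meters) of the seated skeleton used for pose synthesis."""

    trunk: float = 0.55          # mid-hip → neck
    neck_shoulder: float = 0.18
    upper_arm: float = 0.28
    forearm: float = 0.26
    hip_halfwidth: float = 0.12
    head: float = 0.15
    thigh: float = 0.45
    shank: float = 0.42

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ConfigError(f"segment length '{name}' must be positive")

    def scaled(self, factor: float) -> "SkeletonTemplate":
        if factor <= 0:
            raise ConfigError("scale factor must be positive")
        return SkeletonTemplate(
            **{k: v * factor for k, v in self.__dict__.items()}
        )


def _u(psi_deg: float) -> np.ndarray:
    """In-plane unit vector; psi=0 points straight down, +psi rotates forward."""
    psi = math.radians(psi_deg)
    return np.array([math.sin(psi), -math.cos(psi), 0.0])


#: Fixed in-plane direction of the neck→shoulder segment (degrees from
#: straight-down, toward the sagittal forward axis).
_SHOULDER_PSI = 15.0


def angles_to_pose(series: AngleSeries,
                   template: SkeletonTemplate | None = None) -> PoseSequence:
    """Construct a pose sequence whose right-side angles equal ``series``.

    The torso and right-arm chain are laid out in the sagittal (x, y)
    plane: the trunk tilts forward by the trunk deviation, the upper arm is
    rotated from the neck→shoulder direction by exactly the shoulder angle
    and the forearm from the upper arm by exactly the vector-convention
    elbow angle, so the angle definitions invert exactly. Vertical is +y.
    """
    tpl = template or SkeletonTemplate()
    frames = []
    for i in range(series.n_frames):
        sh = float(series.theta_shoulder[i])
        el = float(series.theta_elbow[i])
        tr = float(series.theta_trunk[i])
        for name, v in (("shoulder", sh), ("elbow", el), ("trunk", tr)):
            if not (0.0 <= v <= 180.0) or not math.isfinite(v):
                raise ConstructionError(
                    f"frame {i}: {name} angle {v} not constructible (need [0, 180])"
                )
        mid_hip = np.zeros(3)
        l_hip = np.array([0.0, 0.0, tpl.hip_halfwidth])
        r_hip = np.array([0.0, 0.0, -tpl.hip_halfwidth])
        trunk_dir = np.array([math.sin(math.radians(tr)),
                              math.cos(math.radians(tr)), 0.0])
        neck = mid_hip + tpl.trunk * trunk_dir
        psi_arm = _SHOULDER_PSI + sh
        r_shoulder = neck + tpl.neck_shoulder * _u(_SHOULDER_PSI)
        r_elbow = r_shoulder + tpl.upper_arm * _u(psi_arm)
        r_wrist = r_elbow + tpl.forearm * _u(psi_arm + el)
        # static seated remainder
        head = neck + tpl.head * trunk_dir
        spine = mid_hip + (tpl.trunk / 3.0) * trunk_dir
        thorax = mid_hip + (2.0 * tpl.trunk / 3.0) * trunk_dir
        l_shoulder = neck + tpl.neck_shoulder * np.array([0.0, -0.3, 0.954])
        l_elbow = l_shoulder + tpl.upper_arm * np.array([0.1, -0.995, 0.0])
        l_wrist = l_elbow + tpl.forearm * np.array([0.1, -0.995, 0.0])
        joints = {
            "pelvis": mid_hip, "spine": spine, "thorax": thorax,
            "neck": neck, "head": head,
            "l_shoulder": l_shoulder, "r_shoulder": r_shoulder,
            "l_elbow": l_elbow, "r_elbow": r_elbow,
            "l_wrist": l_wrist, "r_wrist": r_wrist,
            "l_hip": l_hip, "r_hip": r_hip,
            "l_knee": l_hip + np.array([tpl.thigh, 0.0, 0.0]),
            "r_knee": r_hip + np.array([tpl.thigh, 0.0, 0.0]),
            "l_ankle": l_hip + np.array([tpl.thigh, -tpl.shank, 0.0]),
            "r_ankle": r_hip + np.array([tpl.thigh, -tpl.shank, 0.0]),
        }
        frames.append(PoseFrame(
            index=i,
            joints={k: tuple(map(float, v)) for k, v in joints.items()},
        ))
    return PoseSequence(
        frames=tuple(frames), fps=series.fps,
        task=series.task if series.task in TASK_LABELS else None,
        group="simulation", up_axis=(0.0, 1.0, 0.0),
    )


def default_profiles() -> dict[str, TaskProfile]:
    """Shipped profiles for the five cabinet tasks.

    Plateau targets sit inside the envelopes characteristic of each task:
    shoulder 140–160° for sliding-door and mid-height work, 130–140° for
    low-level work; interior elbow 110–130° for low reaches (flexed arm)
    against ≥135° for the easier tasks; interior trunk within 165–175°
    (deviation 5–15°), leaning further forward as the target gets lower.
    Severity therefore increases from sliding door through mid drawer, mid
    hinged door and low drawer to low hinged door.
    """
    targets = {
        "sliding_door": (160.0, 155.0, 175.0),
        "mid_drawer": (148.0, 148.0, 172.0),
        "mid_hinged_door": (140.0, 135.0, 170.0),
        "low_drawer": (133.0, 120.0, 167.0),
        "low_hinged_door": (130.0, 115.0, 165.0),
    }
    return {task: TaskProfile(task=task, plateau=plateau)
            for task, plateau in targets.items()}


def generate_sequence(task: str, seed: int,
                      profiles: dict[str, TaskProfile] | None = None,
                      template: SkeletonTemplate | None = None) -> PoseSequence:
    """Convenience: profile lookup → angle series → pose sequence."""
    profiles = profiles or default_profiles()
    if task not in profiles:
        raise ConfigError(
            f"unknown task '{task}'; valid: {', '.join(sorted(profiles))}"
        )
    return angles_to_pose(generate_angle_series(profiles[task], seed), template)
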