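"""Temporal smoothing, risk discretization, phase segmentation and exposure.

Raw per-frame scores are smoothed with a trailing (causal) moving average
of window ``w`` (default 5 frames): partial windows at the start average
over the frames available so far, and invalid (NaN) frames are excluded
from both numerator and denominator. Smoothed scores are discretized to
integer RULA levels 1–7 by round-half-up and to the four action
categories: low (1–2), medium (3–4), high (5–6), very high (7).

Task recordings are partitioned by frame index into approach, execution
and withdrawal phases (half-open intervals, defaults 30/120 for a
150-frame task at 30 fps), and summarised into exposure statistics: the
high-risk exposure fraction is the share of valid frames whose level falls
in the high or very-high bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError

CATEGORIES = ("low", "medium", "high", "very_high")
PHASES = ("approach", "execution", "withdrawal")

#: level → category per the standard action bands.
_LEVEL_CATEGORY = {1: "low", 2: "low", 3: "medium", 4: "medium",
                   5: "high", 6: "high", 7: "very_high"}

DEFAULT_WINDOW = 5
DEFAULT_PHASE_BOUNDARIES = (30, 120)
DEFAULT_EXPOSURE_THRESHOLDS = (0.30, 0.50)
DEFAULT_BINARY_THRESHOLD = 4.0


def smooth(scores: Sequence[float], w: int = DEFAULT_WINDOW) -> np.ndarray:
    """Trailing moving average over the window {t-w+1, ..., t}.

    NaN entries neither contribute to nor are filled by the average: an
    output frame whose whole window is invalid stays NaN. ``w=1`` is the
    identity.
    """
    if w < 1 or int(w) != w:
        raise ConfigError(f"window size must be a positive integer, got {w}")
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("scores must be a non-empty 1-D series")
    if np.all(np.isnan(s)):
        raise ValueError("all frames invalid: nothing to smooth")
    if w == 1:
        return s.copy()
    valid = np.isfinite(s)
    vals = np.where(valid, s, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(valid)])
    t = np.arange(s.size)
    lo = np.maximum(t - w + 1, 0)
    num = csum[t + 1] - csum[lo]
    den = ccnt[t + 1] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return out


def discretize(s: float) -> tuple[int, str]:
    """Map a continuous score in [1, 7] to (integer level, category).

    Round-half-up: 4.49 → 4 (medium), 4.50 → 5 (high).
    """
    if not math.isfinite(s):
        raise ValueError(f"cannot discretize invalid score {s}")
    if s < 1.0 - 1e-9 or s > 7.0 + 1e-9:
        raise ValueError(f"score {s} outside the risk universe [1, 7]")
    level = int(math.floor(s + 0.5))
    level = min(7, max(1, level))
    return level, _LEVEL_CATEGORY[level]


def segment_phases(n_frames: int,
                   boundaries: tuple[int, int] = DEFAULT_PHASE_BOUNDARIES
                   ) -> list[str]:
    """Phase label per frame: [0,b1) approach, [b1,b2) execution, [b2,n) withdrawal."""
    b1, b2 = boundaries
    if not (0 < b1 < b2):
        raise ConfigError(f"phase boundaries must satisfy 0 < b1 < b2, got {boundaries}")
    return [
        "approach" if i < b1 else ("execution" if i < b2 else "withdrawal")
        for i in range(n_frames)
    ]


@dataclass(frozen=True)
class TrajectoryFrame:
    """One frame of a risk trajectory (NaN scores mark invalid frames)."""

    frame_index: int
    s_raw: float
    s_smooth: float
    level: int | None
    category: str | None
    phase: str

    @property
    def valid(self) -> bool:
        return math.isfinite(self.s_smooth)


@dataclass(frozen=True)
class RiskTrajectory:
    frames: tuple[TrajectoryFrame, ...]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def build_trajectory(raw_scores: Sequence[float],
                     w: int = DEFAULT_WINDOW,
                     boundaries: tuple[int, int] = DEFAULT_PHASE_BOUNDARIES,
                     frame_indices: Sequence[int] | None = None,
                     ) -> RiskTrajectory:
    """Assemble raw scores into a smoothed, discretized, phase-labelled trajectory."""
    raw = np.asarray(raw_scores, dtype=float)
    smoothed = smooth(raw, w)
    phases = segment_phases(raw.size, boundaries)
    if frame_indices is None:
        frame_indices = range(raw.size)
    frames = []
    for i, (idx, sr, ss, ph) in enumerate(zip(frame_indices, raw, smoothed, phases)):
        if math.isfinite(ss):
            level, category = discretize(min(7.0, max(1.0, ss)))
        else:
            level, category = None, None
        frames.append(TrajectoryFrame(
            frame_index=int(idx), s_raw=float(sr), s_smooth=float(ss),
            level=level, category=category, phase=ph,
        ))
    return RiskTrajectory(frames=tuple(frames))


@dataclass(frozen=True)
class ExposureSummary:
    """Task-level risk statistics over the valid frames of one trajectory."""

    mean: float
    sd: float
    proportions: dict[str, float]
    exposure: float                    # high + very_high fraction
    per_phase_mean: dict[str, float]   # NaN where a phase has no valid frames
    n_frames: int
    n_valid: int
    above_binary_threshold: float      # fraction with S_smooth > threshold
    binary_threshold: float = DEFAULT_BINARY_THRESHOLD


def exposure_summary(traj: RiskTrajectory,
                     *, use_raw: bool = False,
                     binary_threshold: float = DEFAULT_BINARY_THRESHOLD,
                     ) -> ExposureSummary:
    """Mean/SD, per-category proportions, high-risk exposure, per-phase means.

    Categories are counted on the smoothed levels by default (``use_raw``
    recounts on levels discretized from the raw scores instead).
    """
    scores = np.array(
        [f.s_raw if use_raw else f.s_smooth for f in traj.frames], dtype=float
    )
    valid = np.isfinite(scores)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("trajectory has no valid frames")
    v = scores[valid]
    levels = np.array([discretize(min(7.0, max(1.0, s)))[0] for s in v])
    cats = [_LEVEL_CATEGORY[int(l)] for l in levels]
    proportions = {c: cats.count(c) / n_valid for c in CATEGORIES}
    exposure = proportions["high"] + proportions["very_high"]
    per_phase: dict[str, float] = {}
    for ph in PHASES:
        ph_scores = [
            s for s, f in zip(scores, traj.frames)
            if f.phase == ph and math.isfinite(s)
        ]
        per_phase[ph] = float(np.mean(ph_scores)) if ph_scores else math.nan
    return ExposureSummary(
        mean=float(np.mean(v)),
        sd=float(np.std(v, ddof=1)) if n_valid > 1 else 0.0,
        proportions=proportions,
        exposure=float(exposure),
        per_phase_mean=per_phase,
        n_frames=len(traj),
        n_valid=n_valid,
        above_binary_threshold=float(np.mean(v > binary_threshold)),
        binary_threshold=binary_threshold,
    )


def flag_design_priority(summary: ExposureSummary,
                         thresholds: tuple[float, float] = DEFAULT_EXPOSURE_THRESHOLDS,
                         ) -> str:
    """Classify exposure against (acceptable, critical) thresholds.

    Strictly below the acceptable threshold → ``acceptable``; strictly
    above the critical threshold → ``critical``; otherwise ``elevated``
    (boundaries are exclusive, matching the "<30%" / ">50%" convention).
    """
    acceptable, critical = thresholds
    if not (0.0 < acceptable < critical < 1.0):
        raise ConfigError(
            f"thresholds must satisfy 0 < acceptable < critical < 1, got {thresholds}"
        )
    x = summary.exposure
    if x < acceptable:
        return "acceptable"
    if x > critical:
        return "critical"
    return "elevated"
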