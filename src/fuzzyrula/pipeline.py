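"""End-to-end assessment: pose sequence → risk trajectory → exposure summary."""

from __future__ import annotations

import math
from typing import Sequence

from . import fuzzy, kinematics, temporal
from .pose import PoseSequence


def assess_sequence(
    seq: PoseSequence,
    config: fuzzy.FuzzySystemConfig | None = None,
    *,
    side: str = "right",
    window: int = temporal.DEFAULT_WINDOW,
    boundaries: tuple[int, int] = temporal.DEFAULT_PHASE_BOUNDARIES,
    thresholds: tuple[float, float] = temporal.DEFAULT_EXPOSURE_THRESHOLDS,
    binary_threshold: float = temporal.DEFAULT_BINARY_THRESHOLD,
    use_raw: bool = False,
) -> tuple[temporal.RiskTrajectory, temporal.ExposureSummary, str]:
    """Run the full per-frame pipeline on one sequence.

    Returns the trajectory, its exposure summary and the design-priority
    flag. Frames with missing joints yield invalid entries that propagate
    as NaN through smoothing and are excluded from the summary.
    """
    config = config or fuzzy.default_config()
    angles = kinematics.sequence_angles(seq, side)
    raw = fuzzy.score_sequence(angles, config)
    traj = temporal.build_trajectory(
        raw, w=window, boundaries=boundaries,
        frame_indices=[f.index for f in seq.frames],
    )
    summary = temporal.exposure_summary(
        traj, use_raw=use_raw, binary_threshold=binary_threshold
    )
    flag = temporal.flag_design_priority(summary, thresholds)
    return traj, summary, flag


def summary_to_dict(
    summary: temporal.ExposureSummary,
    flag: str,
    *,
    task: str | None = None,
    group: str | None = None,
    side: str = "right",
    window: int = temporal.DEFAULT_WINDOW,
    boundaries: Sequence[int] = temporal.DEFAULT_PHASE_BOUNDARIES,
    thresholds: Sequence[float] = temporal.DEFAULT_EXPOSURE_THRESHOLDS,
    config_checksum: str | None = None,
) -> dict:
    """Self-describing JSON payload: statistics plus the settings that made them."""
    def _num(x: float):
        return None if (isinstance(x, float) and math.isnan(x)) else x

    return {
        "task": task,
        "group": group,
        "n_frames": summary.n_frames,
        "n_valid": summary.n_valid,
        "mean": summary.mean,
        "sd": summary.sd,
        "proportions": summary.proportions,
        "exposure": summary.exposure,
        "per_phase": {k: _num(v) for k, v in summary.per_phase_mean.items()},
        "priority_flag": flag,
        "above_binary_threshold": summary.above_binary_threshold,
        "params": {
            "side": side,
            "window": window,
            "phase_boundaries": list(boundaries),
            "exposure_thresholds": list(thresholds),
            "binary_threshold": summary.binary_threshold,
            "fuzzy_config_sha256": config_checksum,
        },
    }
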