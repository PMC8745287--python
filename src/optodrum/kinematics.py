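"""Circular kinematics and the two optomotor endpoint metrics.

Angle time series are differentiated with forward differences through the
minimal signed circular displacement (period 360 deg for position, 180 deg
for the axial orientation), scaled by the frame rate to degrees/s with
clockwise positive.  Frames are then *direction-gated*: a frame counts
toward an endpoint only when the mouse moved in the same rotational sense
as the drum, faster than a small dead band that screens out pixel jitter.

The two endpoints are conditional means of absolute angular velocity over
the gated frames:

* **angular orientation speed** -- from the snout-tail (body-axis) angle;
* **angular running speed** -- from the position angle of the body-mass
  center around the arena center.

An empty gated set yields a *missing* metric: "never followed the drum" is
not the same observation as "followed it at speed zero".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .arena import Direction
from .pose import PoseSample
from .stimulus import StimulusSample


@dataclass(frozen=True)
class KinematicSample:
    """Per-frame angular velocities (deg/s, CW positive) and gating flags."""

    frame_index: int
    position_velocity: Optional[float] = None
    orientation_velocity: Optional[float] = None
    stim_direction: Direction = Direction.UNKNOWN
    position_matched: bool = False
    orientation_matched: bool = False


@dataclass(frozen=True)
class TrialResult:
    """Endpoint metrics and QC for one trial (one processed video)."""

    samples: Tuple[KinematicSample, ...]
    angular_orientation_speed: Optional[float]
    angular_running_speed: Optional[float]
    matched_frame_counts: Tuple[int, int]  # (orientation, position)
    qc: Dict[str, int] = field(default_factory=dict)


def angular_difference(a: float, b: float, period: float) -> float:
    """Minimal signed displacement from angle ``a`` to ``b`` modulo ``period``.

    Result lies in ``(-period/2, period/2]``, clockwise (increasing angle)
    positive.  Position angles use period 360; axial orientation angles
    use period 180.
    """
    if not (period > 0) or not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError(f"invalid period {period} or non-finite angles")
    d = (b - a) % period
    if d > period / 2:
        d -= period
    return d


def velocities(
    poses: Sequence[PoseSample], frame_rate: float
) -> List[KinematicSample]:
    """Forward-difference angular velocities, assigned to the earlier frame.

    ``v_t = angular_difference(theta_t, theta_{t+1}) * frame_rate``.  The
    last frame, and any difference touching an invalid pose, is missing.
    """
    if frame_rate <= 0:
        raise ValueError(f"frame_rate must be positive, got {frame_rate}")
    out: List[KinematicSample] = []
    for i, pose in enumerate(poses):
        pv: Optional[float] = None
        ov: Optional[float] = None
        if i + 1 < len(poses):
            nxt = poses[i + 1]
            if pose.valid and nxt.valid:
                pv = (
                    angular_difference(pose.position_angle, nxt.position_angle, 360.0)
                    * frame_rate
                )
                ov = (
                    angular_difference(
                        pose.orientation_angle, nxt.orientation_angle, 180.0
                    )
                    * frame_rate
                )
        out.append(KinematicSample(pose.frame_index, pv, ov))
    return out


def _matches(velocity: Optional[float], stim: Direction, dead_band: float) -> bool:
    if velocity is None or stim is Direction.UNKNOWN:
        return False
    if abs(velocity) < dead_band:
        return False
    return (velocity > 0) == (stim is Direction.CW)


def direction_match(
    samples: Sequence[KinematicSample],
    stimulus: Sequence[StimulusSample],
    dead_band: float = 2.0,
) -> List[KinematicSample]:
    """Flag frames where the mouse moved with the drum.

    A channel matches when its velocity is present, at least ``dead_band``
    deg/s in magnitude, and of the same rotational sign as a known stimulus
    direction.  Position and orientation channels are gated independently.
    """
    if len(samples) != len(stimulus):
        raise ValueError(
            f"sample/stimulus length mismatch ({len(samples)} vs {len(stimulus)})"
        )
    out: List[KinematicSample] = []
    for k, s in zip(samples, stimulus):
        out.append(
            replace(
                k,
                stim_direction=s.direction,
                position_matched=_matches(k.position_velocity, s.direction, dead_band),
                orientation_matched=_matches(
                    k.orientation_velocity, s.direction, dead_band
                ),
            )
        )
    return out


def summarize_trial(samples: Sequence[KinematicSample]) -> TrialResult:
    """Endpoint metrics: mean |velocity| over direction-matched frames.

    Each metric is missing when its matched set is empty.  QC counters
    record totals, valid-velocity frames and unknown-stimulus frames.
    """
    if len(samples) == 0:
        raise ValueError("summarize_trial requires at least one sample")
    pos_vals = [
        abs(s.position_velocity) for s in samples if s.position_matched
    ]
    ori_vals = [
        abs(s.orientation_velocity) for s in samples if s.orientation_matched
    ]
    qc = {
        "frames_total": len(samples),
        "frames_with_velocity": sum(
            1 for s in samples if s.position_velocity is not None
        ),
        "frames_stimulus_unknown": sum(
            1 for s in samples if s.stim_direction is Direction.UNKNOWN
        ),
        "matched_orientation_frames": len(ori_vals),
        "matched_position_frames": len(pos_vals),
    }
    return TrialResult(
        samples=tuple(samples),
        angular_orientation_speed=(
            sum(ori_vals) / len(ori_vals) if ori_vals else None
        ),
        angular_running_speed=(sum(pos_vals) / len(pos_vals) if pos_vals else None),
        matched_frame_counts=(len(ori_vals), len(pos_vals)),
        qc=qc,
    )
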