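"""Per-frame drum rotation direction inferred from the stripe band.

The drum motor runs autonomously, so the rotation direction must be read
back from the video itself.  A narrow cut directly above the arena center --
where roughly two stripes are visible and the stripes run vertically -- is
reduced to a 1-D column-mean intensity profile, binarized with a local
(adaptive) threshold, and compared with the previous frame's profile over a
scan of integer lateral shifts.  The best-agreeing shift is the stripe
phase displacement; its sign gives the rotation sense (rightward motion in
the cut above the center is clockwise drum rotation under the package angle
conventions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .arena import ArenaGeometry, Direction
from .pose import FrameImage, to_grayscale


@dataclass(frozen=True)
class StimulusSample:
    """Per-frame stimulus state: direction, stripe shift (px) and confidence."""

    frame_index: int
    direction: Direction = Direction.UNKNOWN
    phase_shift: float = 0.0
    confidence: float = 0.0


class DirectionParams(BaseModel):
    """Direction-detector tunables.

    The adaptive-threshold ``window`` is in profile samples (odd); shifts
    below ``min_shift`` px or matches below ``min_confidence`` agreement are
    reported as UNKNOWN; ``max_shift`` defaults to a quarter of the profile
    length; ``smoothing_window`` frames of centered majority voting remove
    isolated direction flips; ``invert`` accommodates mirrored camera
    mounts by swapping the sign-to-direction mapping.
    """

    model_config = ConfigDict(extra="forbid")

    window: int = Field(15, ge=3)
    min_shift: int = Field(1, ge=1)
    max_shift: Optional[int] = Field(None, ge=1)
    min_confidence: float = Field(0.6, ge=0, le=1)
    smoothing_window: int = Field(5, ge=1)
    invert: bool = False


def extract_stripe_strip(frame: FrameImage, geometry: ArenaGeometry) -> np.ndarray:
    """Column-mean intensity profile of the stripe ROI above the center.

    Returns a float 1-D array whose length is the ROI width.
    """
    gray = to_grayscale(frame)
    h, w = gray.shape
    x, y, rw, rh = geometry.stripe_roi
    if x < 0 or y < 0 or x + rw > w or y + rh > h:
        raise ValueError(
            f"stripe_roi {geometry.stripe_roi} outside frame bounds {w}x{h}"
        )
    roi = gray.pixels[y : y + rh, x : x + rw].astype(float)
    return roi.mean(axis=0)


def binarize_adaptive(profile: np.ndarray, window: int = 15) -> np.ndarray:
    """Adaptive (local-mean) binarization of a 1-D intensity profile.

    Each sample becomes 1 iff it strictly exceeds the mean of its centered
    length-``window`` neighborhood; at the edges the window shrinks to the
    available samples.  Ties (e.g. a constant profile) go to 0.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1:
        raise ValueError("profile must be 1-D")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    n = profile.size
    if n < window:
        raise ValueError(f"profile length {n} shorter than window {window}")
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(profile)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    local_mean = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return (profile > local_mean).astype(np.uint8)


def _agreement(current: np.ndarray, previous: np.ndarray, shift: int) -> float:
    """Fraction of overlap positions where ``current`` equals ``previous``
    displaced right by ``shift`` pixels."""
    n = current.size
    if shift >= 0:
        a = current[shift:]
        b = previous[: n - shift]
    else:
        a = current[: n + shift]
        b = previous[-shift:]
    if a.size == 0:
        return 0.0
    return float(np.mean(a == b))


def infer_direction(
    current: np.ndarray,
    previous: np.ndarray,
    max_shift: int,
    min_shift: int = 1,
    min_confidence: float = 0.6,
    invert: bool = False,
) -> Tuple[Direction, int, float]:
    """Best lateral shift between two binary stripe profiles and its direction.

    Scans integer shifts in ``[-max_shift, +max_shift]`` scoring each by the
    fraction of agreeing overlap positions (a binary cross-correlation).
    Ties are broken toward the smallest ``|shift|``, then the positive one.
    A positive shift means the pattern moved right, i.e. the drum turned
    clockwise (unless ``invert``).  Returns UNKNOWN when ``|shift|`` is
    below ``min_shift`` or agreement below ``min_confidence``.
    """
    current = np.asarray(current)
    previous = np.asarray(previous)
    if current.shape != previous.shape or current.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    n = current.size
    if not (1 <= min_shift <= max_shift < n / 2):
        raise ValueError(
            f"need 1 <= min_shift <= max_shift < len/2 "
            f"(min_shift={min_shift}, max_shift={max_shift}, len={n})"
        )
    shifts = sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s < 0))
    best_shift, best_score = 0, -1.0
    for s in shifts:
        score = _agreement(current, previous, s)
        if score > best_score:
            best_shift, best_score = s, score
    if abs(best_shift) < min_shift or best_score < min_confidence:
        return Direction.UNKNOWN, best_shift, best_score
    rightward = best_shift > 0
    if invert:
        rightward = not rightward
    return (Direction.CW if rightward else Direction.CCW), best_shift, best_score


def _majority_smooth(
    directions: List[Direction], window: int
) -> List[Direction]:
    """Centered majority vote over CW/CCW votes.

    UNKNOWN frames neither vote nor get replaced: smoothing corrects
    isolated flips but never invents a direction where none was detected.
    """
    if window <= 1:
        return list(directions)
    half = window // 2
    out: List[Direction] = []
    n = len(directions)
    for i in range(n):
        if directions[i] is Direction.UNKNOWN:
            out.append(Direction.UNKNOWN)
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        votes_cw = sum(1 for d in directions[lo:hi] if d is Direction.CW)
        votes_ccw = sum(1 for d in directions[lo:hi] if d is Direction.CCW)
        if votes_cw > votes_ccw:
            out.append(Direction.CW)
        elif votes_ccw > votes_cw:
            out.append(Direction.CCW)
        else:
            out.append(directions[i])
    return out


def detect_directions(
    frames: Sequence[FrameImage],
    geometry: ArenaGeometry,
    params: Optional[DirectionParams] = None,
) -> List[StimulusSample]:
    """Per-frame stimulus direction over a frame sequence.

    Frame 0 has no predecessor and is always UNKNOWN.  Directions are
    smoothed with a centered majority vote of ``smoothing_window`` frames to
    suppress isolated flips; shifts and confidences are reported raw.
    """
    if len(frames) < 2:
        raise ValueError("detect_directions requires at least 2 frames")
    params = params or DirectionParams()
    profiles = [
        binarize_adaptive(extract_stripe_strip(f, geometry), params.window)
        for f in frames
    ]
    n = profiles[0].size
    max_shift = params.max_shift if params.max_shift is not None else max(1, n // 4)

    raw: List[StimulusSample] = [StimulusSample(frames[0].frame_index)]
    for i in range(1, len(frames)):
        d, shift, conf = infer_direction(
            profiles[i],
            profiles[i - 1],
            max_shift,
            params.min_shift,
            params.min_confidence,
            params.invert,
        )
        raw.append(StimulusSample(frames[i].frame_index, d, float(shift), conf))

    smoothed = _majority_smooth([s.direction for s in raw], params.smoothing_window)
    return [
        StimulusSample(s.frame_index, d, s.phase_shift, s.confidence)
        for s, d in zip(raw, smoothed)
    ]


def reversal_indices(samples: Sequence[StimulusSample]) -> List[int]:
    """Indices where the (smoothed) direction switches between CW and CCW.

    UNKNOWN frames are skipped: a reversal is recorded at the first known
    frame whose direction differs from the last known one.
    """
    out: List[int] = []
    last: Optional[Direction] = None
    for i, s in enumerate(samples):
        if s.direction is Direction.UNKNOWN:
            continue
        if last is not None and s.direction is not last:
            out.append(i)
        last = s.direction
    return out
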