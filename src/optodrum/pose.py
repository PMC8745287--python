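"""Per-frame mouse segmentation and pose estimation.

The measurement chain per frame is: convert to grayscale, restrict to the
circular monitored area, threshold-and-invert so the (dark) mouse becomes
white foreground, then derive two angles from the white pixels:

* the **position angle** of the centroid relative to the arena center
  (clockwise from the upward vertical, ``[0, 360)``), and
* the **orientation angle** of the body axis -- the major principal axis of
  the white-pixel cloud -- relative to the image vertical (``[0, 180)``).

The principal axis (total-least-squares line through the centroid) is used
for the body axis rather than an ``y``-on-``x`` regression: an ordinary
regression is degenerate for a vertical animal and is not rotation
equivariant, which would contradict the 0-deg-is-vertical convention.

Degenerate frames (too few foreground pixels, centroid at the arena center,
isotropic blob) yield *missing* angles, never fabricated zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .arena import ArenaGeometry, orientation_angle_of_vector, position_angle_of_vector

logger = logging.getLogger(__name__)

#: Rec. 601 luma weights used for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class FrameImage:
    """One video frame: an 8-bit or float grayscale/RGB pixel grid plus timing."""

    pixels: np.ndarray
    frame_index: int = 0
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2-D or 3-D, got {self.pixels.ndim}-D")
        if self.pixels.ndim == 3 and self.pixels.shape[2] not in (3, 4):
            raise ValueError(
                f"color frames must have 3 or 4 channels, got {self.pixels.shape[2]}"
            )
        if self.frame_index < 0:
            raise ValueError("frame_index must be nonnegative")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class PoseSample:
    """Per-frame mouse state; ``valid`` iff both angles were computed."""

    frame_index: int
    position_angle: Optional[float] = None
    orientation_angle: Optional[float] = None
    foreground_count: int = 0
    valid: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "valid",
            self.position_angle is not None and self.orientation_angle is not None,
        )


class SegmentationParams(BaseModel):
    """Segmentation/pose tunables.

    ``threshold`` is the constant 8-bit cut below which a pixel counts as
    mouse (the lighting is controlled, so a constant works); ``min_foreground``
    rejects frames with too few mouse pixels; ``centroid_epsilon`` (px) and
    ``isotropy_tolerance`` (relative eigenvalue gap) mark the two geometric
    degeneracies of the angle definitions.
    """

    model_config = ConfigDict(extra="forbid")

    threshold: float = Field(128.0, gt=0, le=255)
    min_foreground: int = Field(50, ge=1)
    centroid_epsilon: float = Field(1.0, ge=0)
    isotropy_tolerance: float = Field(0.05, ge=0, lt=1)
    largest_component: bool = False
    mask_fill: int = Field(255, ge=0, le=255)


def to_grayscale(frame: FrameImage) -> FrameImage:
    """Convert a color frame to grayscale (0.299 R + 0.587 G + 0.114 B).

    Grayscale input passes through unchanged.  8-bit input stays 8-bit
    (rounded); float input stays float.
    """
    px = frame.pixels
    if px.ndim == 2:
        return frame
    if px.ndim == 3 and px.shape[2] in (3, 4):
        gray = px[..., :3].astype(float) @ _LUMA
        if np.issubdtype(px.dtype, np.integer):
            gray = np.rint(gray).astype(px.dtype)
        return FrameImage(gray, frame.frame_index, frame.time)
    raise ValueError(f"unsupported frame shape {px.shape}")


def apply_circular_mask(
    gray: FrameImage,
    geometry: ArenaGeometry,
    fill: float = 255,
    strict: bool = True,
) -> FrameImage:
    """Keep the closed disc of ``mask_radius`` around the arena center.

    Pixels strictly outside the disc are set to ``fill`` (bright by default,
    so they cannot survive the dark-object segmentation).  A mask circle
    extending beyond the frame raises in strict mode and is clipped with a
    warning otherwise.
    """
    h, w = gray.shape
    cx, cy = geometry.center
    r = geometry.mask_radius
    if cx - r < 0 or cy - r < 0 or cx + r > w - 1 or cy + r > h - 1:
        if strict:
            raise ValueError(
                f"mask circle (center {geometry.center}, radius {r}) exceeds "
                f"frame bounds {w}x{h}"
            )
        logger.warning("mask circle exceeds frame bounds; clipping")
    yy, xx = np.ogrid[:h, :w]
    outside = (xx - cx) ** 2 + (yy - cy) ** 2 > r * r
    out = gray.pixels.copy()
    out[outside] = fill
    return FrameImage(out, gray.frame_index, gray.time)


def segment_mouse(masked: FrameImage, threshold: float = 128.0) -> np.ndarray:
    """Binarize-and-invert: foreground (True) where intensity < threshold.

    The mouse is the darkest object in the monitored area, so after
    inversion it is marked with white pixels.  Pixels exactly at the
    threshold are background (strict less-than).
    """
    if masked.pixels.ndim != 2:
        raise ValueError("segment_mouse expects a grayscale frame")
    return masked.pixels < threshold


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return labels == keep


def position_angle(
    mask: np.ndarray,
    geometry: ArenaGeometry,
    min_foreground: int = 50,
    centroid_epsilon: float = 1.0,
) -> Optional[float]:
    """Position angle of the foreground centroid, degrees in [0, 360).

    Measured clockwise from the upward vertical through the arena center to
    the ray center -> centroid.  Returns ``None`` when there are fewer than
    ``min_foreground`` pixels or the centroid is within ``centroid_epsilon``
    px of the center (direction undefined).
    """
    ys, xs = np.nonzero(mask)
    if xs.size < min_foreground:
        return None
    cx, cy = geometry.center
    dx = xs.mean() - cx
    dy = ys.mean() - cy
    if dx * dx + dy * dy <= centroid_epsilon**2:
        return None
    return position_angle_of_vector(dx, dy)


def orientation_angle(
    mask: np.ndarray,
    min_foreground: int = 50,
    isotropy_tolerance: float = 0.05,
) -> Optional[float]:
    """Body-axis angle from the image vertical, degrees in [0, 180).

    Fits the major principal axis of the foreground pixel cloud -- the line
    through the centroid minimizing summed squared *orthogonal* distances --
    and measures its axial angle from the vertical.  Returns ``None`` for
    sparse masks and for nearly isotropic blobs, where the relative gap
    between the two principal variances falls below ``isotropy_tolerance``.
    """
    ys, xs = np.nonzero(mask)
    if xs.size < min_foreground:
        return None
    x = xs - xs.mean()
    y = ys - ys.mean()
    # second central moments of the pixel cloud
    sxx = float(x @ x)
    syy = float(y @ y)
    sxy = float(x @ y)
    cov = np.array([[sxx, sxy], [sxy, syy]]) / xs.size
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    if lam_major <= 0 or (lam_major - lam_minor) / lam_major < isotropy_tolerance:
        return None
    vx, vy = evecs[:, 1]
    return orientation_angle_of_vector(float(vx), float(vy))


def track_frames(
    frames: Sequence[FrameImage],
    geometry: ArenaGeometry,
    params: Optional[SegmentationParams] = None,
) -> List[PoseSample]:
    """Run the full per-frame pose chain over a frame sequence.

    Frames that fail to decode or that are degenerate yield invalid samples;
    processing always continues.  QC counts are logged at INFO.
    """
    if len(frames) == 0:
        raise ValueError("track_frames requires at least one frame")
    params = params or SegmentationParams()
    samples: List[PoseSample] = []
    n_invalid = 0
    for frame in frames:
        try:
            gray = to_grayscale(frame)
            masked = apply_circular_mask(gray, geometry, fill=params.mask_fill)
            mask = segment_mouse(masked, params.threshold)
            if params.largest_component:
                mask = _largest_component(mask)
            fg = int(mask.sum())
            pos = position_angle(
                mask, geometry, params.min_foreground, params.centroid_epsilon
            )
            ori = orientation_angle(
                mask, params.min_foreground, params.isotropy_tolerance
            )
            samples.append(PoseSample(frame.frame_index, pos, ori, fg))
        except Exception:  # pragma: no cover - defensive; logged and skipped
            logger.exception("frame %d failed; recorded as missing", frame.frame_index)
            samples.append(PoseSample(frame.frame_index))
        if not samples[-1].valid:
            n_invalid += 1
    logger.info(
        "tracked %d frames: %d valid, %d invalid",
        len(samples),
        len(samples) - n_invalid,
        n_invalid,
    )
    return samples
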