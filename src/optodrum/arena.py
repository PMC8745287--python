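"""Apparatus model: arena/stimulus configuration, geometry, and angle conventions.

Angle conventions (shared by every module in the package)
---------------------------------------------------------
* **Position angle** ``theta_pos`` is measured *clockwise* from the upward
  vertical through the arena center, in degrees in ``[0, 360)``: a point
  directly above the center is at 0 deg, directly to the right at 90 deg,
  below at 180 deg, to the left at 270 deg.
* **Orientation angle** ``theta_or`` is the axial angle between the image
  vertical and the animal's body axis, in degrees in ``[0, 180)``:
  0 deg is a vertical body axis, 90 deg a horizontal one.  It is an axis,
  not a vector, so head and tail are interchangeable.
* **Clockwise is positive** for all angular velocities, where clockwise is
  defined in image (camera) coordinates as seen by the overhead camera.

Image coordinates follow the raster convention: ``x`` grows to the right,
``y`` grows downward, so "up" is ``-y``.
"""

from __future__ import annotations

import enum
import math
from typing import Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator


class Direction(str, enum.Enum):
    """Rotation sense in image coordinates as seen from above."""

    CW = "CW"
    CCW = "CCW"
    UNKNOWN = "UNKNOWN"

    def opposite(self) -> "Direction":
        if self is Direction.CW:
            return Direction.CCW
        if self is Direction.CCW:
            return Direction.CW
        return Direction.UNKNOWN

    @property
    def sign(self) -> int:
        """+1 for CW, -1 for CCW, 0 for UNKNOWN (CW-positive convention)."""
        if self is Direction.CW:
            return 1
        if self is Direction.CCW:
            return -1
        return 0


#: Package-wide angle conventions, exposed for documentation and for tests.
ANGLE_CONVENTIONS = {
    "position_angle": "degrees in [0, 360), clockwise from the upward "
    "vertical through the arena center; 0 = above, 90 = right",
    "orientation_angle": "degrees in [0, 180), axial angle from the image "
    "vertical to the body axis; 0 = vertical, 90 = horizontal",
    "velocity_sign": "clockwise positive, in image coordinates",
}


def angle_conventions() -> dict:
    """Return the package-wide angle conventions as a dict of descriptions."""
    return dict(ANGLE_CONVENTIONS)


def position_angle_of_vector(dx: float, dy: float) -> float:
    """Clockwise angle in degrees from the upward vertical to vector (dx, dy).

    ``dx`` points right and ``dy`` points down (raster coordinates), so the
    upward vertical is (0, -1).  Result is in [0, 360).
    """
    return math.degrees(math.atan2(dx, -dy)) % 360.0


def orientation_angle_of_vector(vx: float, vy: float) -> float:
    """Axial angle in degrees from the image vertical to the axis (vx, vy).

    Folds into [0, 180): the axis is undirected.
    """
    return math.degrees(math.atan2(vx, -vy)) % 180.0


class ArenaConfig(BaseModel):
    """Geometry, stimulus and acquisition parameters of the optomotor apparatus.

    Defaults mirror a small optomotor drum: a 22 cm drum lined with vertical
    black/white stripes at 0.2 cycles/degree of visual angle, rotating at
    50 deg/s and reversing direction every 20 s, imaged from above at
    30 frames/s for 480 s recordings.  Every value can be overridden for
    other arenas.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    drum_diameter: float = Field(22.0, gt=0, description="drum diameter, cm")
    drum_height: float = Field(30.0, gt=0, description="drum height, cm")
    cylinder_diameter: float = Field(
        15.0, gt=0, description="inner acrylic cylinder diameter, cm"
    )
    stripe_spatial_frequency: float = Field(
        0.2, gt=0, description="stripe spatial frequency, cycles/degree"
    )
    drum_speed: float = Field(
        50.0, gt=0, description="drum angular speed magnitude, degrees/s"
    )
    alternation_period: float = Field(
        20.0, gt=0, description="duration of each constant-direction bout, s"
    )
    initial_direction: Direction = Direction.CW
    frame_rate: float = Field(30.0, gt=0, description="frames/s")
    recording_length: float = Field(480.0, gt=0, description="s")
    luminance_range: Tuple[int, int] = Field(
        (230, 30),
        description="(background bright, mouse dark) display intensities, 8-bit",
    )

    @model_validator(mode="after")
    def _check(self) -> "ArenaConfig":
        if self.cylinder_diameter >= self.drum_diameter:
            raise ValueError(
                "cylinder_diameter must be smaller than drum_diameter "
                f"({self.cylinder_diameter} >= {self.drum_diameter})"
            )
        if self.initial_direction is Direction.UNKNOWN:
            raise ValueError("initial_direction must be CW or CCW")
        bright, dark = self.luminance_range
        if not (0 <= dark < bright <= 255):
            raise ValueError(
                "luminance_range must be (bright, dark) with 0 <= dark < bright <= 255"
            )
        return self

    @property
    def stripe_cycles(self) -> int:
        """Number of full black/white cycles around the drum.

        ``stripe_spatial_frequency * 360`` must round to a whole number of
        cycles for the pattern to close on itself (72 at the defaults).
        """
        exact = self.stripe_spatial_frequency * 360.0
        n = round(exact)
        if n <= 0 or abs(exact - n) > 1e-6:
            raise ValueError(
                "stripe_spatial_frequency * 360 must be a whole number of "
                f"cycles; got {exact}"
            )
        return int(n)


class ArenaGeometry(BaseModel):
    """Pixel-space geometry of one recording: arena center, tracking mask, stripe ROI.

    ``stripe_roi`` is the rectangular cut directly above the arena center in
    which (roughly) two stripes are visible; it is given as
    ``(x, y, width, height)`` in pixels and must lie outside the circular
    tracking mask.
    """

    model_config = ConfigDict(extra="forbid")

    center: Tuple[float, float] = Field(description="(x, y) of arena center, px")
    mask_radius: float = Field(gt=0, description="tracking-mask radius, px")
    stripe_roi: Tuple[int, int, int, int] = Field(
        description="(x, y, width, height) of the stripe cut, px"
    )

    @model_validator(mode="after")
    def _check(self) -> "ArenaGeometry":
        x, y, w, h = self.stripe_roi
        if w <= 0 or h <= 0:
            raise ValueError("stripe_roi width and height must be positive")
        cx, cy = self.center
        # every ROI corner must lie outside the closed mask disc
        for px, py in ((x, y), (x + w, y), (x, y + h), (x + w, y + h)):
            if (px - cx) ** 2 + (py - cy) ** 2 <= self.mask_radius**2:
                raise ValueError(
                    "stripe_roi must lie fully outside the circular tracking mask"
                )
        return self

    def check_frame(self, shape: Tuple[int, int]) -> None:
        """Validate that mask and ROI fit a frame of the given (H, W) shape."""
        height, width = shape
        x, y, w, h = self.stripe_roi
        if x < 0 or y < 0 or x + w > width or y + h > height:
            raise ValueError(
                f"stripe_roi {self.stripe_roi} exceeds frame bounds {width}x{height}"
            )
        cx, cy = self.center
        if not (0 <= cx < width and 0 <= cy < height):
            raise ValueError(f"arena center {self.center} outside frame")


def default_geometry(frame_size: int = 480) -> ArenaGeometry:
    """Desk-scale default geometry: square frame, centered arena.

    The stripe ROI is a 40 x 12 px band directly above the center, placed in
    the stripe annulus so that about two full stripe cycles are visible at
    the default spatial frequency.
    """
    c = frame_size / 2.0
    mask_radius = frame_size * 200.0 / 480.0
    roi_w, roi_h = 40, 12
    roi_y = int(round(frame_size * 12.0 / 480.0))
    return ArenaGeometry(
        center=(c, c),
        mask_radius=mask_radius,
        stripe_roi=(int(round(c - roi_w / 2)), roi_y, roi_w, roi_h),
    )


def stimulus_direction_schedule(config: ArenaConfig, t: float) -> Direction:
    """Ground-truth drum direction at time ``t`` (seconds).

    The drum rotates in ``initial_direction`` for one alternation period,
    then reverses, alternating for the whole recording.  Bouts are half-open
    ``[k*P, (k+1)*P)``: a boundary instant belongs to the later bout.

    This is the simulator's ground truth only -- the analysis pipeline never
    reads it; direction is inferred from pixels.
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    k = math.floor(t / config.alternation_period)
    if k % 2 == 0:
        return config.initial_direction
    return config.initial_direction.opposite()


def drum_phase(config: ArenaConfig, t: float) -> float:
    """Signed drum rotation (degrees, CW positive) accumulated by time ``t``.

    Integrates the alternation schedule: each full CW+CCW pair nets zero, so
    the phase is periodic with period ``2 * alternation_period``.
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    p = config.alternation_period
    s0 = config.initial_direction.sign
    k = math.floor(t / p)
    r = t - k * p
    if k % 2 == 0:
        return s0 * config.drum_speed * r
    return s0 * config.drum_speed * (p - r)
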