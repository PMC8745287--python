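"""Ground-truthed synthetic optomotor arena.

Renders overhead views of the apparatus -- a bright central platform inside
a circular tracking region, surrounded by an annulus of vertical black and
white stripes that rotates according to the alternation schedule -- plus a
parameterized mouse drawn as a dark ellipse.  Pixels are always derived
from the ground-truth trajectory, never the other way around, so every
stage of the analysis pipeline can be validated against exact truth.

The behavioral model is deliberately minimal: the mouse circles the arena
center at a fixed radius, matching a configurable fraction
(``following_gain``) of the drum's angular speed, reversing ``response_latency``
seconds after each stimulus reversal, with optional per-frame Gaussian
jitter on both angles.  Orientation is tangential to the motion (the body
axis perpendicular to the center ray), which is what a stripe-following
mouse running along the cylinder wall looks like from above.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .arena import ArenaConfig, ArenaGeometry, drum_phase, stimulus_direction_schedule
from .pose import FrameImage

#: Fixed fraction of the mask radius at which the simulated mouse circles.
RADIAL_FRACTION = 0.6

#: Stripe intensities (8-bit).  Black stripes only ever appear outside the
#: tracking mask, so the mouse stays the darkest object inside it.
STRIPE_WHITE = 255
STRIPE_BLACK = 0


class BehaviorParams(BaseModel):
    """Parameters of the simulated mouse's stripe-following behavior."""

    model_config = ConfigDict(extra="forbid")

    following_gain: float = Field(
        1.0, ge=0, le=1, description="fraction of drum speed the mouse tracks"
    )
    response_latency: float = Field(
        0.0, ge=0, description="delay after a reversal before the mouse reverses, s"
    )
    angle_noise_sd: float = Field(
        0.0, ge=0, description="per-frame Gaussian jitter on both angles, degrees"
    )
    body_length: float = Field(60.0, gt=0, description="ellipse major axis, px")
    body_width: float = Field(26.0, gt=0, description="ellipse minor axis, px")
    seed: int = Field(0, ge=0, description="random generator seed")

    @model_validator(mode="after")
    def _check(self) -> "BehaviorParams":
        if self.body_length <= self.body_width:
            raise ValueError("body_length must exceed body_width")
        return self


def strip_pixels_per_degree(geometry: ArenaGeometry) -> float:
    """Lateral px moved in the stripe ROI per degree of drum rotation.

    For the cut directly above the center, a small rotation ``d_psi``
    displaces the pattern horizontally by about ``h * d_psi`` (radians),
    where ``h`` is the height of the ROI midline above the center.
    """
    cx, cy = geometry.center
    _, y, _, h = geometry.stripe_roi
    height_above_center = cy - (y + h / 2.0)
    if height_above_center <= 0:
        raise ValueError("stripe_roi must lie above the arena center")
    return height_above_center * math.pi / 180.0


def _polar_grids(
    shape: Tuple[int, int], center: Tuple[float, float]
) -> Tuple[np.ndarray, np.ndarray]:
    """(position-angle deg, squared radius) of every pixel; cached per call site."""
    h, w = shape
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    alpha = np.degrees(np.arctan2(dx, -dy)) % 360.0
    return alpha, dx * dx + dy * dy


def render_stimulus_frame(
    config: ArenaConfig,
    geometry: ArenaGeometry,
    t: float,
    shape: Tuple[int, int] = (480, 480),
    frame_index: int = 0,
    _grids: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> FrameImage:
    """Render the arena at time ``t`` with no mouse.

    Inside the tracking mask: the bright platform.  Outside: the stripe
    annulus, whose phase equals the initial phase plus the signed drum
    rotation accumulated by ``t`` under the alternation schedule; exactly
    ``config.stripe_cycles`` black/white cycles span the circumference.
    """
    cycles = config.stripe_cycles  # validates integrality
    alpha, r2 = _grids if _grids is not None else _polar_grids(shape, geometry.center)
    psi = drum_phase(config, t)
    s = (((alpha - psi) % 360.0) * cycles / 360.0) % 1.0
    out = np.where(s < 0.5, STRIPE_WHITE, STRIPE_BLACK).astype(np.uint8)
    inside = r2 <= geometry.mask_radius**2
    out[inside] = config.luminance_range[0]
    return FrameImage(out, frame_index, t)


def _draw_mouse(
    img: np.ndarray,
    center: Tuple[float, float],
    orientation_deg: float,
    length: float,
    width: float,
    intensity: int,
) -> None:
    """Rasterize a filled ellipse (in place) with its major axis at the
    given axial angle from the image vertical."""
    cx, cy = center
    a, b = length / 2.0, width / 2.0
    half = int(math.ceil(a)) + 1
    h, w = img.shape
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    th = math.radians(orientation_deg)
    ux, uy = math.sin(th), -math.cos(th)  # unit vector along the body axis
    major = dx * ux + dy * uy
    minor = -dx * uy + dy * ux
    img[y0:y1, x0:x1][(major / a) ** 2 + (minor / b) ** 2 <= 1.0] = intensity


def simulate_mouse(
    config: ArenaConfig,
    behavior: BehaviorParams,
    duration: float,
    geometry: Optional[ArenaGeometry] = None,
) -> pd.DataFrame:
    """Ground-truth trajectory of the simulated mouse.

    The position angle at time ``t`` is ``following_gain`` times the drum
    phase evaluated at ``t - response_latency`` (clamped at 0), plus seeded
    Gaussian jitter; the orientation is tangential (position + 90 deg,
    folded into [0, 180)) with its own jitter draw.  Stimulus truth columns
    record the scheduled direction and the stripe-pattern pixel shift since
    the previous frame in the stripe ROI.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    from .arena import default_geometry

    geometry = geometry or default_geometry()
    n = int(round(duration * config.frame_rate))
    times = np.arange(n) / config.frame_rate
    rng = np.random.default_rng(behavior.seed)
    noise = rng.normal(0.0, behavior.angle_noise_sd, size=(2, n)) if (
        behavior.angle_noise_sd > 0
    ) else np.zeros((2, n))

    phase_at = np.array([drum_phase(config, t) for t in times])
    delayed = np.array(
        [drum_phase(config, max(t - behavior.response_latency, 0.0)) for t in times]
    )
    pos = (behavior.following_gain * delayed + noise[0]) % 360.0
    ori = (pos + 90.0 + noise[1] - noise[0]) % 180.0

    px_per_deg = strip_pixels_per_degree(geometry)
    shift_px = np.zeros(n)
    shift_px[1:] = np.diff(phase_at) * px_per_deg
    directions = [stimulus_direction_schedule(config, t).value for t in times]
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": times,
            "true_position_angle": pos,
            "true_orientation_angle": ori,
            "true_stim_direction": directions,
            "true_stim_phase_shift_px": shift_px,
        }
    )


class SyntheticTrial(Sequence[FrameImage]):
    """Lazily rendered synthetic trial: frames are rasterized on access.

    Behaves as an ordered sequence of :class:`FrameImage`, so it plugs
    directly into ``detect_directions`` / ``track_frames`` without holding
    a whole recording in memory.  Rendering is deterministic: the same
    (config, geometry, behavior, duration, shape) always yields identical
    pixels.
    """

    def __init__(
        self,
        config: ArenaConfig,
        geometry: ArenaGeometry,
        truth: pd.DataFrame,
        shape: Tuple[int, int] = (480, 480),
        behavior: Optional[BehaviorParams] = None,
        with_mouse: bool = True,
    ) -> None:
        self.config = config
        self.geometry = geometry
        self.truth = truth
        self.shape = shape
        self.behavior = behavior
        self.with_mouse = with_mouse and behavior is not None
        self._grids = _polar_grids(shape, geometry.center)

    def __len__(self) -> int:
        return len(self.truth)

    def __getitem__(self, i: int) -> FrameImage:
        if isinstance(i, slice):
            raise TypeError("SyntheticTrial does not support slicing")
        n = len(self)
        if i < 0:
            i += n
        if not 0 <= i < n:
            raise IndexError(i)
        row = self.truth.iloc[i]
        frame = render_stimulus_frame(
            self.config,
            self.geometry,
            float(row.time_s),
            self.shape,
            frame_index=int(row.frame),
            _grids=self._grids,
        )
        if self.with_mouse:
            cx, cy = self.geometry.center
            r = RADIAL_FRACTION * self.geometry.mask_radius
            th = math.radians(row.true_position_angle)
            mouse_center = (cx + r * math.sin(th), cy - r * math.cos(th))
            _draw_mouse(
                frame.pixels,
                mouse_center,
                float(row.true_orientation_angle),
                self.behavior.body_length,
                self.behavior.body_width,
                self.config.luminance_range[1],
            )
        return frame


def render_trial(
    config: ArenaConfig,
    geometry: ArenaGeometry,
    behavior: Optional[BehaviorParams],
    duration: float,
    shape: Tuple[int, int] = (480, 480),
    out_dir: Optional[Path] = None,
) -> Tuple[SyntheticTrial, pd.DataFrame]:
    """Render a synthetic trial and its ground-truth table.

    With ``behavior=None`` a stimulus-only trial (no mouse) is produced.
    When ``out_dir`` is given, frames are written as numbered PNGs along
    with ``ground_truth.csv``.
    """
    bp = behavior or BehaviorParams(following_gain=0.0)
    truth = simulate_mouse(config, bp, duration, geometry)
    trial = SyntheticTrial(
        config, geometry, truth, shape, behavior, with_mouse=behavior is not None
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
            import imageio.v3 as iio

            for frame in trial:
                iio.imwrite(
                    out_dir / f"frame_{frame.frame_index:06d}.png", frame.pixels
                )
            truth.to_csv(out_dir / "ground_truth.csv", index=False)
        except OSError as exc:
            raise OSError(f"failed writing trial to {out_dir}: {exc}") from exc
    return trial, truth
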