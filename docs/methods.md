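# Methods

## Measurement model

The optomotor assay films a mouse from directly above while a striped drum
rotates around it, reversing direction on a fixed schedule. The package
treats one recording as a sequence of frames at a constant frame rate and
estimates three per-frame quantities — drum direction, mouse position
angle, mouse orientation angle — and from them two trial endpoints.

### Angle conventions

All angles live in image (raster) coordinates: `x` right, `y` down, so
"up" is `-y`, and *clockwise on screen* is the positive rotational sense.

* position angle `θ_pos = atan2(dx, -dy) mod 360°` for the vector
  `(dx, dy)` from the arena center to the foreground centroid — 0° above
  the center, 90° to the right;
* orientation angle `θ_or ∈ [0°, 180°)` is the axial angle of the body
  axis from the vertical — 0° vertical, 90° horizontal. It is an axis,
  not a heading: the package never distinguishes head from tail.

These conventions make a clockwise screen rotation by φ add φ to both
angles (mod 360° and 180° respectively), a property the test suite checks
directly.

### Stimulus direction from pixels

The drum motor runs autonomously, so direction is inferred from the video.
A rectangular cut directly above the arena center (default 40 × 12 px in a
480 × 480 frame, sized so about two stripe cycles are visible at the
default spatial frequency) is averaged down its columns into a 1-D
profile. The profile is binarized against a local mean (window 15
samples, shrinking at the edges; strict `>` so constant regions become 0)
— an adaptive threshold, immune to slow illumination gradients across the
band. Consecutive binary profiles are compared at every integer lateral
shift `s ∈ [-max_shift, +max_shift]` (default `max_shift` = profile
length / 4) by the fraction of agreeing positions in the overlap; the
argmax is the stripe phase shift. Ties go to the smallest |s|, then the
positive one, which favors "no motion" and keeps the scan deterministic.
Rightward pattern motion in a cut above the center is clockwise drum
rotation (an `invert` flag accommodates mirrored camera mounts).

A frame is UNKNOWN when the best shift is under `min_shift` (1 px) or the
agreement under `min_confidence` (0.6). A centered 5-frame majority vote
removes isolated flips but never overwrites an UNKNOWN frame. With the
default geometry the expected shift at 50 °/s and 30 fps is ≈ 6.5 px per
frame against a stripe period of ≈ 19 px, so the quarter-length shift
bound also excludes the one-period alias.

### Pose

Color frames are reduced by the Rec. 601 luminance (0.299 R + 0.587 G +
0.114 B). A closed circular mask keeps the monitored area (boundary
pixels inside); everything outside is filled bright so it cannot survive
segmentation. Foreground is `intensity < threshold` (default 128 of 255;
the arena lighting is controlled, so a constant threshold suffices —
the value is a config input). No morphological cleanup is applied by
default, matching the minimal measurement chain; a `largest_component`
switch exists for noisy recordings.

The position angle comes from the foreground centroid; the orientation
from the major principal axis of the foreground pixel cloud — the
total-least-squares (orthogonal-distance) line through the centroid,
computed from the second central moments. An ordinary y-on-x regression
would be degenerate for a vertical animal and not rotation-equivariant,
which would contradict the 0°-is-vertical convention; the principal axis
is the rotation-equivariant reading of a "regression line through the
white pixels".

Frames are *invalid* (angles missing, never zero-filled) when foreground
falls below `min_foreground` (50 px), when the centroid is within
`centroid_epsilon` (1 px) of the center, or when the two principal
variances agree within `isotropy_tolerance` (relative gap < 0.05 — an
isotropic blob has no axis).

### Kinematics and endpoints

Velocities are forward differences assigned to the earlier frame:
`v_t = wrap(θ_{t+1} − θ_t) × frame_rate`, where `wrap` is the minimal
signed circular displacement — period 360° for position, 180° for the
axial orientation (so an orientation step from 179° to 1° reads +2°, not
−178°). Any difference touching an invalid pose is missing, as is the
last frame.

A frame is direction-matched when its velocity is present, at least
`dead_band` (2 °/s) in magnitude, and of the same sign as a known stimulus
direction; pixel quantization of a stationary blob otherwise produces
spurious matched frames. The endpoints are means of |v| over the matched
frames of each channel — a conditional mean over stimulus-following
movement, with the absolute value making CW and CCW bouts commensurable.
An empty matched set yields a missing metric. Optional centered
moving-median smoothing of velocities (window 5) is off by default.

## Synthetic arena

The simulator emulates the apparatus defaults: 72 stripe cycles
(0.2 cycles/degree × 360°) around an annulus outside the tracking mask,
rotating at 50 °/s with direction reversal every 20 s; a bright platform
(intensity 230) inside the mask; a mouse rendered as a dark ellipse
(intensity 30, default 60 × 26 px) — strictly the darkest object inside
the mask, so segmentation is well-posed by construction. Frames default
to 480 × 480 px with a 200 px mask radius: desk-scale geometry rather
than the camera's native 1920 × 1080, chosen for rendering speed and
fully configurable.

The behavioral model has three parameters: `following_gain` g ∈ [0, 1]
(the position angle is g × the drum phase, evaluated with a
`response_latency` delay), and `angle_noise_sd`, per-frame Gaussian
jitter added to both angles from a seeded generator. Orientation is
tangential (position + 90°), i.e. the animal runs along the cylinder
wall. The radial distance is fixed at 0.6 × mask radius. Rendering is a
pure function of the ground-truth table, so truth and pixels can never
disagree, and trials are byte-reproducible given (config, behavior, seed).

What the simulator does **not** model: fur texture and photometric noise
(a per-pixel noise flag exists but is off by default), shadows, lens
distortion, radial excursions, rearing, grooming, or any non-following
behavior beyond the gain/latency/noise triple. Passing tests on synthetic
trials therefore validate the *measurement chain* — direction detection,
segmentation geometry, angle estimation, gating arithmetic — not
robustness to the full variability of live recordings.

A consequence worth knowing when interpreting real data: with per-frame
angle jitter σ, differencing at frame rate f injects velocity noise of
about √2·σ·f (≈ 42 °/s for σ = 1° at 30 fps). Direction gating then
preferentially keeps frames whose noise points with the stimulus, which
inflates the conditional mean toward the noise scale when the true
following speed is comparable to it. The endpoints are comparative
measures under matched recording conditions, not unbiased speed
estimates under heavy tracking noise.

## Numerical choices

* Bout boundaries are half-open `[kP, (k+1)P)`: a boundary instant belongs
  to the later bout (plain floor arithmetic, no special cases).
* Segmentation uses strict `<` at the threshold; adaptive binarization
  strict `>` at the local mean; ties therefore never oscillate.
* The circular-displacement wrap returns values in `(−period/2, period/2]`
  — the half-period tie maps to the positive side.
* The initial drum direction is not observable from the schedule alone and
  is a required configuration choice (documented default: CW).
* Simulation problem sizes used by the validation script — a 60 s
  recovery trial (1800 frames) and a 120 s reversal-timing run (3600
  frames) — were chosen as the shortest recordings that contain many
  alternation cycles; endpoints are per-frame means, so they are
  insensitive to further lengthening.

## Known limitations

* One animal per arena; no identity or occlusion handling.
* Orientation is axial: running direction along the body axis is not
  resolved, which is sufficient for the endpoints but not for gaze
  analysis.
* Sub-pixel stripe phase is not estimated (integer-pixel shifts suffice
  for direction); drum speed in °/s is never recovered from pixels.
* Group-level statistics across animals or sessions are out of scope; the
  per-trial summary CSV/JSON is the hand-off point.
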