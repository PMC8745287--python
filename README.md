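# optodrum

Quantification of the mouse **optomotor response** from overhead arena
video. The optomotor reflex — involuntary head/body following of rotating
high-contrast stripes — is a standard behavioral readout of visual
function: an animal that resolves the grating turns with it. `optodrum`
processes recordings from a small optomotor drum (a rotating cylinder
lined with vertical black/white stripes surrounding a stationary platform,
filmed from above) and reports the two assay endpoints used for
statistical analysis, together with full per-frame traces.

## What it computes

For each frame the package recovers:

1. **Drum rotation direction** (CW / CCW / unknown), read back from the
   pixels rather than trusted from the motor: a cut directly above the
   arena center, where about two stripes are visible, is reduced to a 1-D
   column-mean profile, binarized by adaptive (local-mean) thresholding,
   and compared with the previous frame over a scan of lateral shifts
   (binary cross-correlation). The best-agreeing shift gives the stripe
   displacement; its sign gives the direction.
2. **Mouse position angle** θ_pos ∈ [0°, 360°): the image is converted to
   grayscale, restricted to a circular mask over the monitored area, and
   thresholded-and-inverted so the dark mouse becomes white foreground;
   θ_pos is the clockwise angle from the upward vertical through the arena
   center to the foreground centroid (0° above, 90° right).
3. **Mouse orientation angle** θ_or ∈ [0°, 180°): the axial angle between
   the image vertical and the major principal axis of the foreground
   pixels (0° vertical, 90° horizontal).

Forward differences of the two angle series (minimal signed circular
displacement × frame rate, clockwise positive) give per-frame angular
velocities. Frames are then **direction-gated**: a frame counts only when
the mouse moved in the same rotational sense as the drum, faster than a
small dead band (default 2 °/s). The endpoints are conditional means of
absolute angular velocity over the gated frames:

* **angular orientation speed** — from the snout–tail (body-axis) angle;
* **angular running speed** — from the position angle of the body-mass
  center around the arena center.

A **synthetic arena** renders ground-truthed videos of the whole apparatus
(default: 22 cm drum, stripes at 0.2 cycles/degree — 72 cycles per turn —
rotating at 50 °/s and reversing every 20 s, 30 frames/s) with a
parameterized mouse (following gain, response latency, angle jitter), so
every stage is testable without recorded data. A small utility also
computes the composite EAU (experimental autoimmune uveoretinitis)
clinical score, the mean of the optic-disc, retinal-vessel and
retinal-tissue grades of one eye.

## Worked example

Render a 10 s synthetic trial in which the mouse follows the drum at 75 %
of the drum speed, then analyze it:

```bash
optodrum simulate --out-dir demo_trial --duration 10 --gain 0.75 --seed 7
optodrum track demo_trial --output-dir demo_out
```

prints

```json
{
  "angular_orientation_speed_degps": 37.502843172595604,
  "angular_running_speed_degps": 37.50166642462513,
  "matched_orient_frames": 298,
  "matched_pos_frames": 298
}
```

Both endpoints recover 0.75 × 50 °/s = 37.5 °/s; 298 of the 300 frames
were direction-matched (frame 0 has no predecessor for direction
detection, the last frame no successor for differencing).
`demo_out/` also receives the per-frame CSV
(`frame, time_s, position_angle_deg, orientation_angle_deg, foreground_px,
valid, stim_direction, stim_phase_shift_px, stim_confidence,
position_velocity_degps, orientation_velocity_degps, position_matched,
orientation_matched`) and a summary JSON with QC counters.

The same chain is available as a library:

```python
import optodrum as od
from optodrum.config import RunConfig

cfg = RunConfig()
trial, truth = od.render_trial(cfg.arena, cfg.geometry,
                               od.BehaviorParams(following_gain=0.75, seed=7), 10.0)
result, table = od.analyze_frames(trial, cfg)
print(result.angular_running_speed)   # 37.50...
```

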