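"""Frame readers and tabular writers.

Recordings are accepted either as a directory of numbered still images
(PNG/TIFF, the lossless path) or as an AVI/MP4 container, which requires an
ffmpeg-capable imageio plugin at run time.  Frame-level results go to CSV
(angles with 3 decimals, velocities with 2, missing values as empty
fields), trial summaries to JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .arena import Direction
from .kinematics import KinematicSample, TrialResult
from .pose import FrameImage, PoseSample
from .stimulus import StimulusSample

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}
_VIDEO_SUFFIXES = {".avi", ".mp4", ".mov", ".mkv"}


def read_frames(
    path: Union[str, Path],
    frame_rate: float = 30.0,
    frame_range: Optional[Tuple[int, int]] = None,
) -> List[FrameImage]:
    """Read a recording into a list of frames.

    ``path`` may be a directory of numbered images (sorted by filename) or
    a video container.  ``frame_range`` is half-open ``(start, stop)`` in
    frame indices of the source; indices and times always refer to the
    source, not the slice.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise IOError(f"no image frames found in directory {path}")
        if frame_range is not None:
            start, stop = frame_range
            files_idx = [(i, f) for i, f in enumerate(files) if start <= i < stop]
        else:
            files_idx = list(enumerate(files))
        import imageio.v3 as iio

        frames = []
        for i, f in files_idx:
            try:
                px = np.asarray(iio.imread(f))
            except Exception as exc:
                raise IOError(f"failed to read frame {f}: {exc}") from exc
            frames.append(FrameImage(px, i, i / frame_rate))
        return frames
    if path.suffix.lower() in _VIDEO_SUFFIXES:
        return _read_video(path, frame_rate, frame_range)
    raise IOError(
        f"unsupported input {path}: expected a frame directory or one of "
        f"{sorted(_VIDEO_SUFFIXES)}"
    )


def _read_video(
    path: Path, frame_rate: float, frame_range: Optional[Tuple[int, int]]
) -> List[FrameImage]:
    import imageio.v3 as iio

    try:
        meta = iio.immeta(path, exclude_applied=False)
    except Exception as exc:
        raise IOError(
            f"cannot read video {path} (an ffmpeg-capable imageio plugin is "
            f"required for AVI/MP4; a PNG frame directory always works): {exc}"
        ) from exc
    container_fps = meta.get("fps")
    if container_fps and abs(container_fps - frame_rate) > 1e-6:
        logger.warning(
            "container frame rate %.3f overridden by configured %.3f",
            container_fps,
            frame_rate,
        )
    frames: List[FrameImage] = []
    start, stop = frame_range if frame_range is not None else (0, None)
    for i, px in enumerate(iio.imiter(path)):
        if i < start:
            continue
        if stop is not None and i >= stop:
            break
        frames.append(FrameImage(np.asarray(px), i, i / frame_rate))
    if not frames:
        raise IOError(f"no frames decoded from {path}")
    return frames


def _fmt(value: Optional[float], decimals: int) -> str:
    return "" if value is None else f"{value:.{decimals}f}"


def frame_table(
    poses: Sequence[PoseSample],
    stimulus: Sequence[StimulusSample],
    kinematics: Sequence[KinematicSample],
    frame_rate: float,
) -> pd.DataFrame:
    """Assemble the frame-level results table (one row per frame)."""
    if not (len(poses) == len(stimulus) == len(kinematics)):
        raise ValueError("poses, stimulus and kinematics must be frame-aligned")
    rows = []
    for p, s, k in zip(poses, stimulus, kinematics):
        rows.append(
            {
                "frame": p.frame_index,
                "time_s": p.frame_index / frame_rate,
                "position_angle_deg": p.position_angle,
                "orientation_angle_deg": p.orientation_angle,
                "foreground_px": p.foreground_count,
                "valid": p.valid,
                "stim_direction": s.direction.value,
                "stim_phase_shift_px": s.phase_shift,
                "stim_confidence": s.confidence,
                "position_velocity_degps": k.position_velocity,
                "orientation_velocity_degps": k.orientation_velocity,
                "position_matched": k.position_matched,
                "orientation_matched": k.orientation_matched,
            }
        )
    return pd.DataFrame(rows)


def write_frame_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the frame-level table: UTF-8 CSV, angles %.3f, velocities %.2f,
    missing values as empty fields."""
    out = df.copy()
    for col in ("position_angle_deg", "orientation_angle_deg", "time_s"):
        out[col] = [_fmt(v, 3) for v in out[col]]
    for col in ("position_velocity_degps", "orientation_velocity_degps"):
        out[col] = [_fmt(v, 2) for v in out[col]]
    out["stim_phase_shift_px"] = [f"{v:.0f}" for v in out["stim_phase_shift_px"]]
    out["stim_confidence"] = [f"{v:.4f}" for v in out["stim_confidence"]]
    out.to_csv(path, index=False, encoding="utf-8")


def summary_dict(result: TrialResult, video_id: str = "") -> dict:
    """JSON-ready trial summary: endpoint metrics, matched counts, QC."""
    return {
        "video_id": video_id,
        "angular_orientation_speed_degps": result.angular_orientation_speed,
        "angular_running_speed_degps": result.angular_running_speed,
        "matched_orient_frames": result.matched_frame_counts[0],
        "matched_pos_frames": result.matched_frame_counts[1],
        "qc": dict(result.qc),
    }


def write_summary_json(
    result: TrialResult, path: Union[str, Path], video_id: str = "", extra: dict = None
) -> None:
    payload = summary_dict(result, video_id)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def append_session_row(result: TrialResult, path: Union[str, Path], video_id: str) -> None:
    """Append one summary row per video to a session-level CSV."""
    path = Path(path)
    row = pd.DataFrame(
        [
            {
                "video_id": video_id,
                "angular_orientation_speed_degps": result.angular_orientation_speed,
                "angular_running_speed_degps": result.angular_running_speed,
                "matched_orient_frames": result.matched_frame_counts[0],
                "matched_pos_frames": result.matched_frame_counts[1],
                "frames_total": result.qc.get("frames_total"),
                "frames_valid": result.qc.get("frames_with_velocity"),
            }
        ]
    )
    row.to_csv(path, mode="a", header=not path.exists(), index=False)
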