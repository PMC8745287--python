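"""Run configuration: one validated object tying every stage's tunables together.

Loaded from JSON or YAML; unknown keys are rejected by name so a typo in a
config file fails loudly instead of silently falling back to a default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .arena import ArenaConfig, ArenaGeometry, default_geometry
from .pose import SegmentationParams
from .stimulus import DirectionParams


class KinematicsParams(BaseModel):
    """Velocity/gating tunables: jitter dead band (deg/s) and optional
    centered moving-median smoothing of velocities (off by default)."""

    model_config = ConfigDict(extra="forbid")

    dead_band: float = Field(2.0, ge=0)
    median_smoothing: bool = False
    median_window: int = Field(5, ge=3)


class IOParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    input_path: Optional[str] = None
    output_dir: str = "."
    frame_range: Optional[Tuple[int, int]] = None


class RunConfig(BaseModel):
    """Complete configuration of one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    arena: ArenaConfig = Field(default_factory=ArenaConfig)
    geometry: ArenaGeometry = Field(default_factory=default_geometry)
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    direction: DirectionParams = Field(default_factory=DirectionParams)
    kinematics: KinematicsParams = Field(default_factory=KinematicsParams)
    io: IOParams = Field(default_factory=IOParams)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    Every violation is reported with the offending key path.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    elif path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        raise ValueError(f"config must be .json or .yaml, got {path.suffix}")
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ValueError(
            f"invalid configuration {path}:\n" + "\n".join(lines)
        ) from exc


def dump_config(config: RunConfig) -> dict:
    """Serialize a config (defaults included) to a plain dict; the result
    round-trips through :func:`load_config`."""
    return config.model_dump(mode="json")
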