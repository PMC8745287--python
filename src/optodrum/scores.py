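"""Composite EAU clinical score.

In experimental autoimmune uveoretinitis (EAU), fundus inflammation is
graded separately for the optic disc, the retinal vessels and the retinal
tissue (each typically 0-4 with half-point steps permitted).  The overall
clinical score of an eye is the plain arithmetic mean of the three
component grades, reported unrounded.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Default maximum grade for each component.
DEFAULT_MAX_GRADE = 4.0

_COMPONENTS = ("optic_disc", "retinal_vessels", "retinal_tissue")


class EauComponentScores(BaseModel):
    """Per-eye component grades: optic disc, retinal vessels, retinal tissue."""

    model_config = ConfigDict(extra="forbid")

    optic_disc: float = Field(ge=0)
    retinal_vessels: float = Field(ge=0)
    retinal_tissue: float = Field(ge=0)
    max_grade: float = Field(DEFAULT_MAX_GRADE, gt=0)

    @model_validator(mode="after")
    def _bounded(self) -> "EauComponentScores":
        for name in _COMPONENTS:
            v = getattr(self, name)
            if v > self.max_grade:
                raise ValueError(f"{name}={v} exceeds max_grade={self.max_grade}")
        return self


def eau_composite(
    scores: Union[EauComponentScores, tuple, list],
    max_grade: float = DEFAULT_MAX_GRADE,
) -> float:
    """Composite EAU score: mean of the three component grades, unrounded.

    Accepts an :class:`EauComponentScores` or a (disc, vessels, tissue)
    triple; out-of-range grades raise a validation error.
    """
    if not isinstance(scores, EauComponentScores):
        disc, vessels, tissue = scores
        scores = EauComponentScores(
            optic_disc=disc,
            retinal_vessels=vessels,
            retinal_tissue=tissue,
            max_grade=max_grade,
        )
    return (scores.optic_disc + scores.retinal_vessels + scores.retinal_tissue) / 3.0


def score_table(df: pd.DataFrame, max_grade: float = DEFAULT_MAX_GRADE) -> pd.DataFrame:
    """Append a ``composite`` column to a table of component grades.

    The table must carry ``optic_disc``, ``retinal_vessels`` and
    ``retinal_tissue`` columns (any identifier columns, e.g. ``animal_id``
    and ``eye``, pass through untouched).
    """
    missing = [c for c in _COMPONENTS if c not in df.columns]
    if missing:
        raise ValueError(f"missing component columns: {missing}")
    out = df.copy()
    out["composite"] = [
        eau_composite((row.optic_disc, row.retinal_vessels, row.retinal_tissue),
                      max_grade=max_grade)
        for row in df.itertuples()
    ]
    return out


def score_csv(in_path: Union[str, Path], out_path: Union[str, Path],
              max_grade: float = DEFAULT_MAX_GRADE) -> pd.DataFrame:
    """Read a component-grade CSV, append the composite, write it back out."""
    df = pd.read_csv(in_path)
    out = score_table(df, max_grade=max_grade)
    out.to_csv(out_path, index=False)
    return out
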