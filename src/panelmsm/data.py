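"""Panel observation records and their validation.

An observation record is one sighting of one individual: an identifier, a
time in days since the study epoch, a residency state code 1-7, fixed
covariates, and gender.  A panel dataset is a collection of such records for
one gender stratum; the model is always fitted within a stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import (
    BIRTH_AREA_LEVELS,
    ETHNICITY_LEVELS,
    GENDER_LEVELS,
    SLUM_LEVELS,
)
from .states import DEATH, N_STATES

#: Canonical column order of the observation CSV schema.
SCHEMA = (
    "individual_id",
    "time_days",
    "state",
    "gender",
    "slum_area",
    "ethnicity",
    "area_of_birth",
    "age",
)


class ValidationError(ValueError):
    """A schema or consistency violation in observation records."""


def validate_records(df: pd.DataFrame, line_offset: int = 2) -> None:
    """Validate an observation DataFrame; raise with row diagnostics.

    ``line_offset`` maps DataFrame positions to file line numbers (header is
    line 1 when reading a CSV).
    """
    missing = set(SCHEMA) - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError("dataset contains no observation records")

    state = df["state"].to_numpy()
    bad = ~np.isin(state, range(1, N_STATES + 1))
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"line {k + line_offset}: unknown state code {state[k]!r} (must be 1-7)"
        )
    for col, levels in (
        ("gender", GENDER_LEVELS),
        ("slum_area", SLUM_LEVELS),
        ("ethnicity", ETHNICITY_LEVELS),
        ("area_of_birth", BIRTH_AREA_LEVELS),
    ):
        bad = ~df[col].isin(levels).to_numpy()
        if bad.any():
            k = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"line {k + line_offset}: unknown {col} {df[col].iloc[k]!r}"
            )
    if (df["age"].to_numpy(float) < 0).any():
        k = int(np.flatnonzero(df["age"].to_numpy(float) < 0)[0])
        raise ValidationError(f"line {k + line_offset}: negative age")

    # per-individual time ordering and terminal-death rule; preserve file order
    pos = np.arange(len(df))
    for ind, g in df.assign(_pos=pos).groupby("individual_id", sort=False):
        t = g["time_days"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            k = int(g["_pos"].to_numpy()[np.flatnonzero(np.diff(t) <= 0)[0] + 1])
            raise ValidationError(
                f"line {k + line_offset}: non-increasing time for individual {ind!r}"
            )
        s = g["state"].to_numpy()
        if np.any(s[:-1] == DEATH):
            k = int(g["_pos"].to_numpy()[np.flatnonzero(s[:-1] == DEATH)[0] + 1])
            raise ValidationError(
                f"line {k + line_offset}: record after death for individual {ind!r}"
            )


@dataclass
class PanelDataset:
    """Validated observation records for one gender stratum."""

    records: pd.DataFrame
    gender_stratum: str

    def __post_init__(self):
        if self.gender_stratum not in GENDER_LEVELS:
            raise ValidationError(f"unknown gender stratum {self.gender_stratum!r}")
        validate_records(self.records)
        if not (self.records["gender"] == self.gender_stratum).all():
            raise ValidationError("records do not all match the stratum's gender")
        self.records = self.records.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.records["individual_id"].nunique()

    def individuals(self):
        """Iterate (id, sub-DataFrame) in file order."""
        return self.records.groupby("individual_id", sort=False)


def split_by_gender(df: pd.DataFrame) -> dict:
    """Split a mixed observation DataFrame into per-gender PanelDatasets."""
    validate_records(df)
    out = {}
    for gender in GENDER_LEVELS:
        sub = df[df["gender"] == gender]
        if len(sub):
            out[gender] = PanelDataset(sub.reset_index(drop=True), gender)
    return out
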