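"""Fixed covariates of the residency model and their dummy encoding.

Four covariates enter every transition intensity: slum area, ethnicity,
area of birth (all categorical with fixed level sets) and age in years
(continuous, untransformed).  Reference levels are Korogocho, Kamba and
Nairobi non-slum, so hazard ratios read as contrasts against those baselines.
Gender is deliberately absent: it is a stratifier (two separate model fits),
never a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SLUM_LEVELS = ("Korogocho", "Viwandani")
ETHNICITY_LEVELS = ("Kamba", "Kikuyu", "Luhya", "Luo", "Other")
BIRTH_AREA_LEVELS = ("Nairobi non-slum", "Rural Kenya", "Same DSA slum", "Other")
GENDER_LEVELS = ("Female", "Male")

#: Dummy-encoded design columns, in fixed order (1 + 4 + 3 + 1 = 9 terms).
DESIGN_TERMS: tuple[str, ...] = (
    "slum:Viwandani",
    "ethnicity:Kikuyu",
    "ethnicity:Luhya",
    "ethnicity:Luo",
    "ethnicity:Other",
    "area_of_birth:Rural Kenya",
    "area_of_birth:Same DSA slum",
    "area_of_birth:Other",
    "age",
)


@dataclass(frozen=True)
class CovariateVector:
    """One individual's fixed covariates."""

    slum_area: str = "Korogocho"
    ethnicity: str = "Kamba"
    area_of_birth: str = "Nairobi non-slum"
    age: float = 0.0

    def __post_init__(self):
        if self.slum_area not in SLUM_LEVELS:
            raise ValueError(f"unknown slum area {self.slum_area!r}")
        if self.ethnicity not in ETHNICITY_LEVELS:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")
        if self.area_of_birth not in BIRTH_AREA_LEVELS:
            raise ValueError(f"unknown area of birth {self.area_of_birth!r}")
        if not (np.isfinite(self.age) and self.age >= 0):
            raise ValueError("age must be a non-negative finite number of years")

    def encode(self) -> tuple[np.ndarray, tuple[str, ...]]:
        """Dummy-encode against the reference levels; returns (values, terms)."""
        vals = np.array(
            [
                1.0 * (self.slum_area == "Viwandani"),
                1.0 * (self.ethnicity == "Kikuyu"),
                1.0 * (self.ethnicity == "Luhya"),
                1.0 * (self.ethnicity == "Luo"),
                1.0 * (self.ethnicity == "Other"),
                1.0 * (self.area_of_birth == "Rural Kenya"),
                1.0 * (self.area_of_birth == "Same DSA slum"),
                1.0 * (self.area_of_birth == "Other"),
                float(self.age),
            ]
        )
        return vals, DESIGN_TERMS


def design_matrix(df: pd.DataFrame, terms=DESIGN_TERMS) -> np.ndarray:
    """Dummy-encode a roster DataFrame (one row per individual).

    Expects columns ``slum_area``, ``ethnicity``, ``area_of_birth``, ``age``
    as needed by ``terms``.  Unknown category levels raise with the offending
    value named.
    """
    cols = []
    for term in terms:
        if term == "age":
            cols.append(df["age"].to_numpy(float))
            continue
        var, level = term.split(":", 1)
        if var == "slum":
            var = "slum_area"
        levels = {
            "slum_area": SLUM_LEVELS,
            "ethnicity": ETHNICITY_LEVELS,
            "area_of_birth": BIRTH_AREA_LEVELS,
        }[var]
        bad = set(df[var].unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown {var} level(s): {sorted(map(str, bad))}")
        cols.append((df[var] == level).to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))
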