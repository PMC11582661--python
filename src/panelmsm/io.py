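"""CSV readers/writers and run configuration.

The observation schema is a plain CSV with header columns
``individual_id, time_days, state, gender, slum_area, ethnicity,
area_of_birth, age``; state codes are the 1-based integers of the state
diagram and times are day offsets from the study epoch.  Run configuration
is YAML.  Every numeric artifact written by the pipeline embeds the seed and
a hash of the configuration in a leading comment line, so identical
(config, seed) runs produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .covariates import DESIGN_TERMS
from .data import SCHEMA, PanelDataset, ValidationError, split_by_gender


def read_observations(path) -> dict:
    """Read and validate an observation CSV; returns per-gender datasets.

    Schema violations are reported with 1-based file line numbers (the
    header is line 1).
    """
    df = pd.read_csv(path, comment="#")
    if len(df) == 0:
        raise ValidationError(f"{path}: file contains a header but no records")
    try:
        return split_by_gender(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_observations(datasets, path) -> None:
    """Write one or several per-gender datasets back to the CSV schema."""
    if isinstance(datasets, PanelDataset):
        datasets = {datasets.gender_stratum: datasets}
    df = pd.concat([d.records for d in datasets.values()], ignore_index=True)
    df.to_csv(path, index=False, columns=list(SCHEMA))


def write_truth_params(truth: dict, path) -> None:
    """Serialize generating parameters as tidy CSV (gender, pair, term, value)."""
    rows = []
    for gender, params in truth.items():
        for pair, v in params.baseline_log_intensity.items():
            rows.append((gender, pair[0], pair[1], "baseline_log_intensity", v))
        for (pair, term), v in params.coefficients.items():
            rows.append((gender, pair[0], pair[1], term, v))
    pd.DataFrame(rows, columns=["gender", "from_state", "to_state",
                                "term", "value"]).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run."""

    seed: int = 0
    out_dir: str = "artifacts"
    input_path: str | None = None      # read observations; None -> simulate
    stratum: str = "both"              # female | male | both
    death_mode: str = "exact"
    covariate_terms: tuple = DESIGN_TERMS
    rate_stratifiers: tuple = ("gender",)
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self):
        self.covariate_terms = tuple(self.covariate_terms)
        self.rate_stratifiers = tuple(self.rate_stratifiers)
        if self.stratum not in ("female", "male", "both"):
            raise ValueError("stratum must be female, male or both")
        if self.death_mode not in ("exact", "panel"):
            raise ValueError("death_mode must be exact or panel")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable short hash of the scientific configuration (seed included).

        The output directory does not affect results and is excluded.
        """
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None,
                float_format: str = "%.10g") -> None:
    """Write a tidy CSV artifact with an embedded seed/config stamp."""
    path = Path(path)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# seed={config.seed} config={config.digest()}\n")
        df.to_csv(fh, index=False, float_format=float_format)
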