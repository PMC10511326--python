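"""Table schemas, configuration, and structured run logging.

The canonical interchange format is a long CSV with columns
``reef_id, year, variable, value`` (survey and driver tables share it);
configuration travels as YAML.  Validation errors always name the
offending row or field.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["read_survey_table", "write_long_table", "read_config", "write_config", "RunConfig"]

LONG_COLUMNS = ["reef_id", "year", "variable", "value"]
PERCENT_COVER_VARS = {"coral_cover", "cca_cover", "reef_builder_cover"}


def read_survey_table(path) -> pd.DataFrame:
    """Read and validate a long-format survey/driver CSV.

    Checks the column set, bounds percent-cover variables to [0, 100], and
    rejects duplicate (reef, year, variable) records.
    """
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(LONG_COLUMNS)
    if unknown or set(LONG_COLUMNS) - set(df.columns):
        raise ValueError(
            f"{path}: expected columns {LONG_COLUMNS}, found {list(df.columns)}"
        )
    dup = df.duplicated(subset=["reef_id", "year", "variable"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate record for reef {row.reef_id}, year {row.year}, "
            f"variable {row.variable}"
        )
    covers = df[df["variable"].isin(PERCENT_COVER_VARS)]
    vals = pd.to_numeric(covers["value"], errors="coerce")
    bad = covers[(vals < 0) | (vals > 100)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"{path}: cover value {row.value} outside [0, 100] "
            f"(reef {row.reef_id}, year {row.year}, row {bad.index[0]})"
        )
    return df


def write_long_table(df: pd.DataFrame, path) -> None:
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[LONG_COLUMNS].to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of one staged pipeline run."""

    stages: list = field(default_factory=lambda: ["simulate", "trajectory", "heatwave", "persistence", "scenarios"])
    out_dir: str = "landsea_run"
    seed: int = 0
    n_cells: int = 400
    n_reefs: int = 80
    years: tuple = (2003, 2019)
    heatwave_year: int = 2015
    heatwave_anomaly_C: float = 2.2
    trajectory_cutoff: float = 3.0
    n_perm: int = 999
    max_predictors_heatwave: int = 5
    max_predictors_ordinal: int = 4
    prune_threshold: float = 0.7
    keep_preferences: list = field(
        default_factory=lambda: [
            "dhw",
            "peak_rainfall",
            "phytoplankton",
            "scraper_biomass",
            "grazer_biomass",
            "wastewater",
        ]
    )
    sqrt_transforms: list = field(
        default_factory=lambda: [
            "total_fish_biomass",
            "herbivore_biomass",
            "scraper_biomass",
            "grazer_biomass",
            "wastewater",
            "urban_runoff",
            "nutrients",
            "phytoplankton",
            "peak_rainfall",
        ]
    )
    fourth_root_transforms: list = field(default_factory=lambda: ["sediment"])

    def to_yaml(self) -> str:
        d = asdict(self)
        d["years"] = list(self.years)
        return yaml.safe_dump(d, sort_keys=False)


_VALID_STAGES = ("simulate", "drivers", "trajectory", "heatwave", "persistence", "scenarios")


def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.years = tuple(cfg.years)
    bad = [s for s in cfg.stages if s not in _VALID_STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}; valid stages are {_VALID_STAGES}")
    return cfg


def write_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(cfg.to_yaml())


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=str))
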