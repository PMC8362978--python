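"""File formats, configuration and the end-to-end pipeline.

All tables are plain CSV with explicit headers; age groups and periods
are keyed by their start year (5-year, left-closed bins; 80 means the
open 80+ interval).  Floats are written with 12 significant digits so
write-then-read round-trips are lossless at that precision.  Each
pipeline run emits a machine-readable JSON manifest (config hash, seed,
library versions, output checksums); logging goes to stderr.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .apc import APCDesign, fit_apc
from .correction import CorrectionFactors, CorrectionResult, correct_pipeline
from .rates import (
    MortalityGrid,
    StandardPopulation,
    rates_table,
    segi_world_20plus,
)
from .selection import sequential_table
from .synthetic import SyntheticConfig, generate_records, person_years_grid

log = logging.getLogger("apcmort")

FLOAT_FORMAT = "%.12g"

RECORD_COLUMNS = ["year", "age_years", "icd_revision", "icd_code"]


class TableFormatError(ValueError):
    """A CSV input violates its declared schema."""


def read_death_records(path: str | Path) -> pd.DataFrame:
    """Read a record-level death CSV (year, age_years, icd_revision, icd_code[, unit, sex]).

    Malformed rows are rejected with their 1-based file line numbers.
    An empty file with a valid header yields an empty table.
    """
    df = pd.read_csv(path, dtype={"icd_code": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    bad: list[int] = []
    for col in ("year", "age_years", "icd_revision"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad.extend(df.index[vals.isna()] + 2)  # +2: header line + 1-based
        df[col] = vals
    bad.extend(df.index[~df["icd_revision"].isin([9, 10])] + 2)
    bad.extend(df.index[df["age_years"] < 0] + 2)
    if bad:
        raise TableFormatError(f"{path}: malformed rows at lines {sorted(set(bad))}")
    for col in ("year", "age_years", "icd_revision"):
        df[col] = df[col].astype(int)
    if "unit" not in df.columns:
        df["unit"] = ""
    return df


def read_cause_tabulation(path: str | Path) -> pd.DataFrame:
    """Read a pre-tabulated cause-class CSV (unit, year, age_group_start, cause_class, count)."""
    from .correction import CAUSE_COLUMNS

    df = pd.read_csv(path)
    required = ["year", "age_group_start", "cause_class", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = sorted((df.index[counts.isna() | (counts < 0)] + 2).tolist())
    if bad:
        raise TableFormatError(f"{path}: negative or non-numeric counts at lines {bad}")
    unknown = set(df["cause_class"]) - set(CAUSE_COLUMNS)
    if unknown:
        raise TableFormatError(f"{path}: unknown cause classes {sorted(unknown)}")
    if "unit" not in df.columns:
        df["unit"] = ""
    wide = (
        df.pivot_table(
            index=["unit", "year", "age_group_start"],
            columns="cause_class",
            values="count",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=CAUSE_COLUMNS, fill_value=0.0)
        .astype(float)
        .reset_index()
    )
    wide.columns.name = None
    return wide


def read_correction_factors(path: str | Path) -> CorrectionFactors:
    """Read completeness factors from CSV (unit, decade, factor) or YAML."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
        return _factors_from_mapping(raw)
    df = pd.read_csv(path)
    for col in ("decade", "factor"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    if "unit" not in df.columns:
        df["unit"] = "*"
    table: dict[str, dict[int, float]] = {}
    for row in df.itertuples(index=False):
        table.setdefault(str(row.unit), {})[int(row.decade)] = float(row.factor)
    return CorrectionFactors(table)


def _factors_from_mapping(raw: Mapping[Any, Any]) -> CorrectionFactors:
    if all(isinstance(v, (int, float)) for v in raw.values()):
        return CorrectionFactors.uniform({int(k): float(v) for k, v in raw.items()})
    return CorrectionFactors(
        {str(u): {int(k): float(v) for k, v in t.items()} for u, t in raw.items()}
    )


def read_standard_population(path: str | Path) -> StandardPopulation:
    df = pd.read_csv(path, comment="#")
    for col in ("age_group_start", "weight"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    return StandardPopulation(
        age_group_starts=df["age_group_start"].to_numpy(),
        weights=df["weight"].to_numpy(),
        label=str(path),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_grid_csv(result: CorrectionResult, path: str | Path,
                   person_years: np.ndarray | None = None) -> None:
    """Write the corrected-grid CSV dialect.

    Columns: unit, period_start, age_group_start, deaths_raw,
    deaths_corrected[, person_years].
    """
    table = result.table.copy()
    if person_years is not None:
        py = pd.DataFrame(
            {
                "period_start": np.repeat(result.period_starts, len(result.age_group_starts)),
                "age_group_start": np.tile(result.age_group_starts, len(result.period_starts)),
                "person_years": np.asarray(person_years).T.ravel(),
            }
        )
        table = table.merge(py, on=["period_start", "age_group_start"], how="left")
    write_table(table, path)


def read_grid_csv(path: str | Path, unit: str | None = None) -> MortalityGrid:
    """Read a corrected-grid CSV (with person_years) back into a MortalityGrid."""
    df = pd.read_csv(path)
    required = ["period_start", "age_group_start", "deaths_corrected", "person_years"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    if unit is not None:
        df = df[df["unit"] == unit]
    ages = np.sort(df["age_group_start"].unique())
    periods = np.sort(df["period_start"].unique())
    D = df.pivot_table(index="age_group_start", columns="period_start",
                       values="deaths_corrected").loc[ages, periods].to_numpy()
    N = df.pivot_table(index="age_group_start", columns="period_start",
                       values="person_years").loc[ages, periods].to_numpy()
    unit_label = str(df["unit"].iloc[0]) if "unit" in df.columns and len(df) else ""
    return MortalityGrid(D, N, ages, periods, unit=unit_label)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run (simulate .. model-table)."""

    seed: int = 0
    outdir: str = "apcmort-out"
    unit: str = "SYN"
    age_group_starts: list[int] = field(default_factory=lambda: list(range(20, 85, 5)))
    period_starts: list[int] = field(default_factory=lambda: list(range(1980, 2020, 5)))
    reference_period: int = 1995
    reference_cohort: int = 1945
    correction_fraction: float = 0.5
    correction_factors: dict[int, float] | None = None  # decade -> factor
    standard_population: str | None = None  # path; default Segi 20+
    mode: str = "factor"
    spline_df: tuple[int, int, int] = (8, 8, 8)
    synthetic: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ages = np.asarray(self.age_group_starts)
        periods = np.asarray(self.period_starts)
        if np.any(np.diff(ages) <= 0) or np.any(np.diff(periods) <= 0):
            raise ValueError("age-group and period starts must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "spline_df" in raw:
            raw["spline_df"] = tuple(raw["spline_df"])
        if "correction_factors" in raw and raw["correction_factors"] is not None:
            raw["correction_factors"] = {
                int(k): float(v) for k, v in raw["correction_factors"].items()
            }
        return cls(**raw)

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            n_age_groups=len(self.age_group_starts),
            n_periods=len(self.period_starts),
            first_age_start=int(self.age_group_starts[0]),
            first_period_start=int(self.period_starts[0]),
            unit=self.unit,
            seed=self.seed,
            **self.synthetic,
        )

    def factors(self) -> CorrectionFactors:
        if self.correction_factors is not None:
            return CorrectionFactors.uniform(self.correction_factors)
        # default: inverse of the synthetic generator's completeness
        comp = self.synthetic_config().completeness
        return CorrectionFactors.uniform({d: 1.0 / c for d, c in comp.items()})

    def design(self) -> APCDesign:
        return APCDesign(
            age_group_starts=np.asarray(self.age_group_starts),
            period_starts=np.asarray(self.period_starts),
            reference_period=self.reference_period,
            reference_cohort=self.reference_cohort,
            mode=self.mode,
            spline_df=tuple(self.spline_df),
        )

    def canonical_yaml(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["spline_df"] = list(d["spline_df"])
        return yaml.safe_dump(d, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """simulate -> correct -> rates -> apc-fit -> model-table, to one directory.

    Returns the paths of all written artifacts.  Re-running with the
    same config reproduces byte-identical numeric outputs (the manifest
    records their checksums).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    log.addHandler(handler)
    stage = "setup"
    try:
        paths: dict[str, Path] = {}

        stage = "simulate"
        log.info("stage simulate: seed=%d", config.seed)
        syn = config.synthetic_config()
        truth = generate_records(syn)
        paths["records"] = outdir / "records.csv"
        write_table(truth.records, paths["records"])

        stage = "correct"
        log.info("stage correct: %d records", len(truth.records))
        factors = config.factors()
        result = correct_pipeline(
            truth.records,
            factors,
            age_group_starts=config.age_group_starts,
            period_starts=config.period_starts,
            fraction=config.correction_fraction,
        )
        N = person_years_grid(syn)
        paths["grid"] = outdir / "corrected_grid.csv"
        write_grid_csv(result, paths["grid"], person_years=N)

        stage = "rates"
        log.info("stage rates")
        _, corrected = result.grids(unit=config.unit)
        grid = MortalityGrid(
            corrected, N, config.age_group_starts, config.period_starts, unit=config.unit
        )
        std = (
            read_standard_population(config.standard_population)
            if config.standard_population
            else segi_world_20plus()
        )
        paths["rates"] = outdir / "rates.csv"
        write_table(rates_table(grid, std=std), paths["rates"])

        stage = "apc-fit"
        log.info("stage apc-fit: mode=%s", config.mode)
        design = config.design()
        fit = fit_apc(grid, design)
        paths["apc_fit"] = outdir / "apc_fit.json"
        paths["apc_fit"].write_text(json.dumps(fit.to_dict(), indent=2, sort_keys=True))

        stage = "model-table"
        log.info("stage model-table")
        table = sequential_table(grid, design)
        paths["model_table"] = outdir / "model_table.csv"
        write_table(table.frame, paths["model_table"])
        (outdir / "model_table.txt").write_text(table.to_text() + "\n")
        paths["model_table_txt"] = outdir / "model_table.txt"

        manifest = {
            "apcmort_version": __version__,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                config.canonical_yaml().encode()
            ).hexdigest(),
            "outputs": {k: _sha256(p) for k, p in paths.items()},
            "dropped_unregistered_deaths": truth.dropped_count,
            "best_model": table.best_model,
        }
        paths["manifest"] = outdir / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.info("pipeline complete: %s", outdir)
        return paths
    except Exception as exc:  # annotate which stage died
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
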