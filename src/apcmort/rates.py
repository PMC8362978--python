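"""Mortality rates on an age x period (Lexis) grid.

Age-specific, crude, truncated and directly standardized rates per
100,000 women, plus period-over-period percent changes.  The default
standard population is the Segi world standard (Doll-Hill modification)
restricted to ages 20+, which ships with the package as a CSV.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SCALE = 100_000.0

#: default 5-year design of the analysis: ages 20-24 ... 80+, periods
#: 1980-1984 ... 2015-2019
DEFAULT_AGE_STARTS = tuple(range(20, 85, 5))
DEFAULT_PERIOD_STARTS = tuple(range(1980, 2020, 5))


@dataclass
class MortalityGrid:
    """Deaths and person-years on an I x J age-group x period lattice.

    Parameters
    ----------
    deaths
        I x J matrix of death counts.  Real-valued entries are allowed
        (corrected counts are not rounded).
    person_years
        I x J matrix of person-years at risk, strictly positive.
    age_group_starts
        Start year of each 5-year age group, youngest first; the last
        group is the open interval (80+ in the default design).
    period_starts
        Start calendar year of each 5-year period.
    unit
        Geographic-unit label.
    """

    deaths: np.ndarray
    person_years: np.ndarray
    age_group_starts: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_AGE_STARTS))
    period_starts: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_PERIOD_STARTS))
    unit: str = ""

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        self.age_group_starts = np.asarray(self.age_group_starts, dtype=int)
        self.period_starts = np.asarray(self.period_starts, dtype=int)
        if self.deaths.ndim != 2:
            raise ValueError("deaths must be a 2-D (age x period) matrix")
        if self.deaths.shape != self.person_years.shape:
            raise ValueError(
                f"deaths {self.deaths.shape} and person_years "
                f"{self.person_years.shape} shapes disagree"
            )
        I, J = self.deaths.shape
        if len(self.age_group_starts) != I:
            raise ValueError(f"expected {I} age group labels, got {len(self.age_group_starts)}")
        if len(self.period_starts) != J:
            raise ValueError(f"expected {J} period labels, got {len(self.period_starts)}")
        if np.any(self.deaths < 0):
            raise ValueError("negative death counts")
        if np.any(self.person_years <= 0):
            raise ValueError("person_years must be strictly positive in every cell")

    @property
    def n_age_groups(self) -> int:
        return self.deaths.shape[0]

    @property
    def n_periods(self) -> int:
        return self.deaths.shape[1]


@dataclass
class StandardPopulation:
    """Fixed age structure used as weights in direct standardization."""

    age_group_starts: np.ndarray
    weights: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.age_group_starts = np.asarray(self.age_group_starts, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.age_group_starts):
            raise ValueError("weights and age_group_starts lengths disagree")
        if np.any(self.weights < 0):
            raise ValueError("standard-population weights must be non-negative")
        if not np.any(self.weights > 0):
            raise ValueError("standard population needs at least one positive weight")


def segi_world_20plus() -> StandardPopulation:
    """Segi world standard (Doll-Hill modification), ages 20+ with 80+ open."""
    ref = importlib.resources.files("apcmort.data") / "segi_world_20plus.csv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, comment="#")
    return StandardPopulation(
        age_group_starts=table["age_group_start"].to_numpy(),
        weights=table["weight"].to_numpy(),
        label="Segi world, Doll-Hill modification, ages 20+ with 80+ open",
    )


def age_specific_rates(grid: MortalityGrid, scale: float = DEFAULT_SCALE) -> np.ndarray:
    """Rates per ``scale`` person-years, cell by cell (I x J)."""
    return scale * grid.deaths / grid.person_years


def crude_rate(grid: MortalityGrid, scale: float = DEFAULT_SCALE) -> np.ndarray:
    """All-ages (20+) rate per period: scale * sum(D) / sum(N)."""
    return scale * grid.deaths.sum(axis=0) / grid.person_years.sum(axis=0)


def direct_standardized_rate(age_rates: np.ndarray, std: StandardPopulation) -> float:
    """Directly standardized rate: sum(w_i r_i) / sum(w_i).

    ``age_rates`` is the length-I vector of age-specific rates for one
    period, aligned with the standard population's age groups.
    """
    r = np.asarray(age_rates, dtype=float)
    if r.ndim != 1 or len(r) != len(std.weights):
        raise ValueError(
            f"age_rates has length {r.shape}, standard population has "
            f"{len(std.weights)} groups"
        )
    return float(np.dot(std.weights, r) / std.weights.sum())


def standardized_rates(
    grid: MortalityGrid, std: StandardPopulation, scale: float = DEFAULT_SCALE
) -> np.ndarray:
    """Directly standardized rate for every period of the grid (length J)."""
    if not np.array_equal(std.age_group_starts, grid.age_group_starts):
        raise ValueError("standard population age groups do not match the grid")
    rates = age_specific_rates(grid, scale=scale)
    return np.array([direct_standardized_rate(rates[:, j], std) for j in range(grid.n_periods)])


def percent_change(first: float, last: float) -> float:
    """Percent change 100 * (last - first) / first; requires first > 0."""
    if first <= 0:
        raise ValueError(f"baseline rate must be positive, got {first}")
    return 100.0 * (last - first) / first


def truncated_rate(
    grid: MortalityGrid, age_floor: int, scale: float = DEFAULT_SCALE
) -> np.ndarray:
    """Aggregate rate over age groups at or above ``age_floor``, per period.

    Used for the open interval (80+) but valid for any truncation point
    that coincides with a group boundary.
    """
    starts = grid.age_group_starts
    if age_floor not in starts:
        raise ValueError(f"age_floor {age_floor} is not an age-group start ({list(starts)})")
    sel = starts >= age_floor
    return scale * grid.deaths[sel].sum(axis=0) / grid.person_years[sel].sum(axis=0)


def rates_table(
    grid: MortalityGrid,
    std: StandardPopulation | None = None,
    scale: float = DEFAULT_SCALE,
) -> pd.DataFrame:
    """Tidy rates table: one row per (period, age group | ALL | STD).

    ``ALL`` rows carry the crude 20+ rate, ``STD`` rows the directly
    standardized rate (only when a standard population is given).
    """
    rows = []
    asr = age_specific_rates(grid, scale=scale)
    for j, p in enumerate(grid.period_starts):
        for i, a in enumerate(grid.age_group_starts):
            rows.append((grid.unit, int(p), str(int(a)), asr[i, j]))
        rows.append((grid.unit, int(p), "ALL", crude_rate(grid, scale=scale)[j]))
    if std is not None:
        srs = standardized_rates(grid, std, scale=scale)
        for j, p in enumerate(grid.period_starts):
            rows.append((grid.unit, int(p), "STD", srs[j]))
    return pd.DataFrame(
        rows, columns=["unit", "period_start", "age_group_start", "rate_per_100k"]
    ).sort_values(["period_start", "age_group_start"], kind="stable", ignore_index=True)
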