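"""Correction of under-registered and miscoded cancer death records.

Registry death counts in settings with weak vital statistics understate
cause-specific mortality for three reasons: deaths coded to the
symptoms/ill-defined ICD chapter, cancer deaths coded to unspecified or
secondary sites ("incomplete diagnosis"), and deaths never registered at
all.  This module implements the standard four-step repair for a target
cancer (breast, ICD-9 174 / ICD-10 C50):

i.   proportionally redistribute a fraction (default 50%) of ill-defined
     deaths among defined natural causes;
ii.  proportionally redistribute incomplete-diagnosis cancer deaths
     among specified cancers, within age-group x year strata;
iii. add both breast-cancer shares to the registered breast count;
iv.  multiply by a decade-specific completeness (coverage) factor.

Counts stay real-valued throughout; rounding, if wanted, is a reporting
decision.  Steps i and ii both take their proportional shares from the
original registered tabulation (parallel shares), so the two corrections
do not compound.
"""
from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rates import DEFAULT_AGE_STARTS, DEFAULT_PERIOD_STARTS

log = logging.getLogger(__name__)


class CauseClass(str, enum.Enum):
    """Cause-of-death class used by the correction pipeline."""

    BREAST = "BREAST"
    OTHER_DEFINED_CANCER = "OTHER_DEFINED_CANCER"
    INCOMPLETE_CANCER = "INCOMPLETE_CANCER"
    ILL_DEFINED = "ILL_DEFINED"
    OTHER_DEFINED_NATURAL = "OTHER_DEFINED_NATURAL"
    NON_NATURAL = "NON_NATURAL"


CAUSE_COLUMNS = [c.value for c in CauseClass]
#: classes eligible to receive redistributed ill-defined deaths (step i):
#: defined natural causes, i.e. everything except the two garbage classes
#: and external causes.
DEFINED_NATURAL = [
    CauseClass.BREAST.value,
    CauseClass.OTHER_DEFINED_CANCER.value,
    CauseClass.OTHER_DEFINED_NATURAL.value,
]
#: classes eligible to receive redistributed incomplete-diagnosis deaths
#: (step ii): cancers of specified site.
SPECIFIED_CANCER = [CauseClass.BREAST.value, CauseClass.OTHER_DEFINED_CANCER.value]

#: canonical incomplete-diagnosis code roots (deduplicated)
_ICD9_INCOMPLETE = {195, 196, 197, 198, 199}
_ICD10_INCOMPLETE = {"C76", "C77", "C78", "C79", "C80", "C97"}

_ICD9_RE = re.compile(r"^(\d{3})")
_ICD9_E_RE = re.compile(r"^E\d{3}")
_ICD10_RE = re.compile(r"^([A-Z])(\d{2})")


class ClassificationError(ValueError):
    """Raised for ICD codes that cannot be parsed for their revision."""


def classify_cause(icd_code: str, icd_revision: int) -> CauseClass:
    """Map an ICD-9 or ICD-10 underlying-cause code to its CauseClass.

    Subcodes are truncated to the 3-character root ("C509" -> "C50",
    "174.9" -> "174").  The mapping is total over syntactically valid
    codes of either revision.
    """
    code = str(icd_code).strip().upper().replace(".", "")
    if icd_revision == 9:
        if _ICD9_E_RE.match(code):  # external-cause supplementary chapter
            return CauseClass.NON_NATURAL
        if code.startswith("V"):  # supplementary factors, natural by exclusion
            return CauseClass.OTHER_DEFINED_NATURAL
        m = _ICD9_RE.match(code)
        if not m:
            raise ClassificationError(f"unparseable ICD-9 code {icd_code!r}")
        root = int(m.group(1))
        if root == 174:
            return CauseClass.BREAST
        if root in _ICD9_INCOMPLETE:
            return CauseClass.INCOMPLETE_CANCER
        if 780 <= root <= 799:
            return CauseClass.ILL_DEFINED
        if 800 <= root <= 999:  # nature-of-injury chapter
            return CauseClass.NON_NATURAL
        if 140 <= root <= 208:
            return CauseClass.OTHER_DEFINED_CANCER
        return CauseClass.OTHER_DEFINED_NATURAL
    if icd_revision == 10:
        m = _ICD10_RE.match(code)
        if not m:
            raise ClassificationError(f"unparseable ICD-10 code {icd_code!r}")
        letter, num = m.group(1), int(m.group(2))
        root = f"{letter}{num:02d}"
        if root == "C50":
            return CauseClass.BREAST
        if root in _ICD10_INCOMPLETE:
            return CauseClass.INCOMPLETE_CANCER
        if letter == "R":
            return CauseClass.ILL_DEFINED
        if letter in "STVWXY":
            return CauseClass.NON_NATURAL
        if letter == "C" or (letter == "D" and num <= 48):
            return CauseClass.OTHER_DEFINED_CANCER
        return CauseClass.OTHER_DEFINED_NATURAL
    raise ClassificationError(f"unknown ICD revision {icd_revision!r}")


def classify_records(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a record table with a ``cause_class`` column.

    ``records`` needs ``icd_code`` and ``icd_revision`` columns; each
    distinct (code, revision) pair is classified once.
    """
    out = records.copy()
    pairs = out[["icd_code", "icd_revision"]].drop_duplicates()
    mapping = {
        (c, r): classify_cause(c, int(r)).value
        for c, r in pairs.itertuples(index=False)
    }
    out["cause_class"] = [
        mapping[(c, r)] for c, r in zip(out["icd_code"], out["icd_revision"])
    ]
    return out


@dataclass
class CorrectionFactors:
    """Decade -> completeness-inverse multiplier, optionally per unit.

    ``factors`` maps a geographic-unit label to ``{decade_start: factor}``;
    the unit ``"*"`` is the fallback for units without their own entry.
    Factors are >= 1 (they inflate registered deaths).
    """

    factors: Mapping[str, Mapping[int, float]]

    @classmethod
    def uniform(cls, by_decade: Mapping[int, float]) -> "CorrectionFactors":
        return cls({"*": dict(by_decade)})

    @classmethod
    def identity(cls, decades: Iterable[int] = (1980, 1990, 2000, 2010)) -> "CorrectionFactors":
        return cls.uniform({d: 1.0 for d in decades})

    def __post_init__(self) -> None:
        for unit, table in self.factors.items():
            for decade, f in table.items():
                if not np.isfinite(f) or f < 1.0:
                    raise ValueError(
                        f"correction factor for unit {unit!r}, decade {decade} "
                        f"must be finite and >= 1, got {f}"
                    )

    def factor(self, year: int, unit: str | None = None) -> float:
        decade = (int(year) // 10) * 10
        table = self.factors.get(unit if unit is not None else "*", self.factors.get("*"))
        if table is None or decade not in table:
            raise KeyError(
                f"no correction factor for unit {unit!r}, decade {decade}"
            )
        return float(table[decade])


def tabulate_records(
    records: pd.DataFrame,
    age_group_starts: Sequence[int] = DEFAULT_AGE_STARTS,
) -> pd.DataFrame:
    """Tabulate classified death records by (unit, year, age group, cause).

    Records younger than the first age group are dropped (the analysis
    starts at 20 years).  Returns a wide table with one column per
    CauseClass and identifier columns ``unit``, ``year``,
    ``age_group_start``.
    """
    starts = np.asarray(age_group_starts, dtype=int)
    df = records if "cause_class" in records.columns else classify_records(records)
    df = df.copy()
    if "unit" not in df.columns:
        df["unit"] = ""
    n_young = int((df["age_years"] < starts[0]).sum())
    if n_young:
        log.info("dropping %d records below age %d", n_young, starts[0])
        df = df[df["age_years"] >= starts[0]]
    idx = np.digitize(df["age_years"].to_numpy(), starts, right=False) - 1
    df["age_group_start"] = starts[idx]
    wide = (
        df.groupby(["unit", "year", "age_group_start"])["cause_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=CAUSE_COLUMNS, fill_value=0)
        .astype(float)
        .reset_index()
    )
    wide.columns.name = None
    return wide


def _stratum_keys(tab: pd.DataFrame, strata: Sequence[str]):
    missing = [s for s in strata if s not in tab.columns]
    if missing:
        raise ValueError(f"stratum columns not in tabulation: {missing}")
    return list(strata)


def redistribute_ill_defined(
    tab: pd.DataFrame,
    fraction: float = 0.5,
    strata: Sequence[str] = ("unit", "year", "age_group_start"),
) -> pd.DataFrame:
    """Step i: move ``fraction`` of ill-defined deaths to defined natural causes.

    Within each stratum, every defined-natural cell gains
    ``fraction * ILL_DEFINED_total * cell / sum(defined-natural cells)``
    and each row's ILL_DEFINED count shrinks by ``fraction``; external
    causes are untouched and the stratum grand total is conserved.
    Strata holding ill-defined deaths but no defined natural deaths are
    left alone with a logged warning.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    out = tab.copy()
    keys = _stratum_keys(out, strata)
    for name, g in out.groupby(keys, dropna=False):
        ill_total = g[CauseClass.ILL_DEFINED.value].sum()
        if ill_total <= 0:
            continue
        den = g[DEFINED_NATURAL].to_numpy().sum()
        if den <= 0:
            log.warning(
                "stratum %s has %.1f ill-defined deaths but no defined natural "
                "deaths; left unredistributed", name, ill_total,
            )
            continue
        mass = fraction * ill_total
        for c in DEFINED_NATURAL:
            out.loc[g.index, c] = g[c] + mass * g[c] / den
        out.loc[g.index, CauseClass.ILL_DEFINED.value] = (
            g[CauseClass.ILL_DEFINED.value] * (1.0 - fraction)
        )
    return out


def redistribute_incomplete_cancer(
    tab: pd.DataFrame,
    strata: Sequence[str] = ("unit", "year", "age_group_start"),
) -> pd.DataFrame:
    """Step ii: move incomplete-diagnosis deaths to specified cancers.

    Within each (age group, year[, unit]) stratum, each specified cancer
    gains ``INCOMPLETE_total * cell / sum(specified-cancer cells)``; the
    incomplete class drops to zero wherever the denominator is nonzero.
    """
    out = tab.copy()
    keys = _stratum_keys(out, strata)
    for name, g in out.groupby(keys, dropna=False):
        inc_total = g[CauseClass.INCOMPLETE_CANCER.value].sum()
        if inc_total <= 0:
            continue
        den = g[SPECIFIED_CANCER].to_numpy().sum()
        if den <= 0:
            log.warning(
                "stratum %s has %.1f incomplete-diagnosis deaths but no "
                "specified cancers; left unredistributed", name, inc_total,
            )
            continue
        for c in SPECIFIED_CANCER:
            out.loc[g.index, c] = g[c] + inc_total * g[c] / den
        out.loc[g.index, CauseClass.INCOMPLETE_CANCER.value] = 0.0
    return out


def apply_completeness(
    counts: pd.Series | np.ndarray,
    years: pd.Series | np.ndarray,
    factors: CorrectionFactors,
    units: pd.Series | None = None,
) -> np.ndarray:
    """Step iv: multiply counts by the decade factor of their year (no rounding)."""
    years = np.asarray(years, dtype=int)
    counts = np.asarray(counts, dtype=float)
    if units is None:
        f = np.array([factors.factor(y) for y in years])
    else:
        f = np.array([factors.factor(y, u) for y, u in zip(years, np.asarray(units))])
    return counts * f


@dataclass
class CorrectionResult:
    """Raw and corrected breast-cancer death counts on the analysis grid."""

    table: pd.DataFrame  # unit, period_start, age_group_start, deaths_raw, deaths_corrected
    age_group_starts: np.ndarray
    period_starts: np.ndarray

    def grids(self, unit: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(raw, corrected) I x J matrices for one unit (or the only one)."""
        t = self.table
        if unit is not None:
            t = t[t["unit"] == unit]
        elif t["unit"].nunique() > 1:
            raise ValueError("several units present; pass unit=...")
        raw = np.zeros((len(self.age_group_starts), len(self.period_starts)))
        cor = np.zeros_like(raw)
        a_idx = {a: i for i, a in enumerate(self.age_group_starts)}
        p_idx = {p: j for j, p in enumerate(self.period_starts)}
        for row in t.itertuples(index=False):
            raw[a_idx[row.age_group_start], p_idx[row.period_start]] = row.deaths_raw
            cor[a_idx[row.age_group_start], p_idx[row.period_start]] = row.deaths_corrected
        return raw, cor


def correct_tabulation(
    tab: pd.DataFrame,
    factors: CorrectionFactors,
    age_group_starts: Sequence[int] = DEFAULT_AGE_STARTS,
    period_starts: Sequence[int] = DEFAULT_PERIOD_STARTS,
    fraction: float = 0.5,
    ill_defined_strata: Sequence[str] = ("unit", "year", "age_group_start"),
) -> CorrectionResult:
    """Run steps i-iv on a cause-class tabulation; see :func:`correct_pipeline`."""
    breast = CauseClass.BREAST.value
    step_i = redistribute_ill_defined(tab, fraction=fraction, strata=ill_defined_strata)
    step_ii = redistribute_incomplete_cancer(tab)
    gain_i = step_i[breast] - tab[breast]
    gain_ii = step_ii[breast] - tab[breast]
    work = tab[["unit", "year", "age_group_start"]].copy()
    work["deaths_raw"] = tab[breast]
    summed = tab[breast] + gain_i + gain_ii  # step iii
    work["deaths_corrected"] = apply_completeness(
        summed, work["year"], factors, units=work["unit"]
    )
    pstarts = np.asarray(period_starts, dtype=int)
    if (work["year"] < pstarts[0]).any() or (work["year"] >= pstarts[-1] + 5).any():
        raise ValueError("record years fall outside the period grid")
    work["period_start"] = pstarts[np.digitize(work["year"], pstarts) - 1]
    out = (
        work.groupby(["unit", "period_start", "age_group_start"], as_index=False)[
            ["deaths_raw", "deaths_corrected"]
        ]
        .sum()
    )
    # densify: every grid cell present, zero-filled
    full = (
        pd.MultiIndex.from_product(
            [sorted(out["unit"].unique()), pstarts, np.asarray(age_group_starts, int)],
            names=["unit", "period_start", "age_group_start"],
        )
        .to_frame(index=False)
        .merge(out, how="left")
        .fillna({"deaths_raw": 0.0, "deaths_corrected": 0.0})
    )
    return CorrectionResult(
        table=full,
        age_group_starts=np.asarray(age_group_starts, int),
        period_starts=pstarts,
    )


def correct_pipeline(
    records: pd.DataFrame,
    factors: CorrectionFactors,
    age_group_starts: Sequence[int] = DEFAULT_AGE_STARTS,
    period_starts: Sequence[int] = DEFAULT_PERIOD_STARTS,
    fraction: float = 0.5,
    ill_defined_strata: Sequence[str] = ("unit", "year", "age_group_start"),
) -> CorrectionResult:
    """Full correction of record-level deaths to a corrected breast grid.

    corrected = (registered breast
                 + breast share of step i, computed on the registered counts
                 + breast share of step ii, computed on the registered counts)
                * decade completeness factor,
    tabulated on the I x J age-group x period grid.  Classification is
    performed if the records carry no ``cause_class`` column.
    """
    tab = tabulate_records(records, age_group_starts=age_group_starts)
    return correct_tabulation(
        tab,
        factors,
        age_group_starts=age_group_starts,
        period_starts=period_starts,
        fraction=fraction,
        ill_defined_strata=ill_defined_strata,
    )
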