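"""Sequential comparison of APC sub-models by deviance.

The six-row ladder

    Age -> Age-drift -> Age-Cohort -> Age-Period-Cohort -> Age-Period -> Age-drift

lets adjacent rows be compared by likelihood-ratio chi-square tests:
going down one line either adds a term (drift, then cohort curvature,
then period curvature) or removes one (cohort curvature, then period
curvature), so each deviance difference is chi-square with the df
difference under the smaller model.  The Age-drift model appears twice
— once against each margin — and both rows share a single fit.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .apc import APCDesign, SubmodelFit, fit_submodel
from .rates import MortalityGrid

ROW_MODELS = ["Age", "Age-drift", "Age-Cohort", "Age-Period-Cohort", "Age-Period", "Age-drift"]
_ROW_KEYS = ["age", "age-drift", "age-cohort", "apc", "age-period", "age-drift"]

SIGNIFICANCE_LEVEL = 0.05


class NestingError(ValueError):
    """Deviance difference is negative beyond tolerance: models not nested."""


def lrt(dev_reduced: float, df_reduced: int, dev_full: float, df_full: int) -> float:
    """Upper-tail chi-square p-value for nested Poisson models.

    Returns NaN when the models have equal df (no test possible).
    """
    ddf = df_reduced - df_full
    if ddf < 0:
        raise ValueError("reduced model must have at least as many residual df")
    ddev = dev_reduced - dev_full
    if ddev < -1e-8:
        raise NestingError(
            f"deviance of the reduced model is smaller ({dev_reduced} < {dev_full}); "
            "models are not nested"
        )
    if ddf == 0:
        return float("nan")
    return float(chi2.sf(max(ddev, 0.0), ddf))


@dataclass
class ModelComparisonTable:
    """Deviance/df/p ladder over the six sequential sub-models."""

    frame: pd.DataFrame  # model, df_resid, deviance, p_value
    best_model: str
    fits: dict[str, SubmodelFit]

    def to_text(self) -> str:
        """Fixed-width report (Models, Df, Residual Deviance, p (>|Chi|))."""
        lines = [f"{'Models':<20}{'Df':>5}  {'Residual Deviance':>18}  {'p (>|Chi|)':>11}"]
        for row in self.frame.itertuples(index=False):
            p = "" if np.isnan(row.p_value) else (
                "<0.0001" if row.p_value < 1e-4 else f"{row.p_value:.4f}"
            )
            lines.append(
                f"{row.model:<20}{row.df_resid:>5}  {row.deviance:>18.2f}  {p:>11}"
            )
        lines.append(f"Best-fitting model (adjacent tests at {SIGNIFICANCE_LEVEL}): {self.best_model}")
        return "\n".join(lines)


def sequential_table(grid: MortalityGrid, design: APCDesign | None = None) -> ModelComparisonTable:
    """Fit the five distinct sub-models and build the six-row ladder.

    p-values compare each row with the previous one; the final Age-drift
    row is tested against Age-Period.  A best-fitting model is chosen as
    the smallest model that the adjacent-line tests at the 0.05 level do
    not reject in favour of a larger one.
    """
    if design is None:
        design = APCDesign(
            age_group_starts=grid.age_group_starts, period_starts=grid.period_starts
        )
    fits = {m: fit_submodel(grid, design, m) for m in
            ("age", "age-drift", "age-cohort", "apc", "age-period")}

    def _lrt(reduced: str, full: str) -> float:
        r, f = fits[reduced], fits[full]
        return lrt(r.deviance, r.df_resid, f.deviance, f.df_resid)

    p_values = [
        float("nan"),
        _lrt("age", "age-drift"),
        _lrt("age-drift", "age-cohort"),
        _lrt("age-cohort", "apc"),
        _lrt("age-period", "apc"),
        _lrt("age-drift", "age-period"),
    ]
    frame = pd.DataFrame(
        {
            "model": ROW_MODELS,
            "df_resid": [fits[k].df_resid for k in _ROW_KEYS],
            "deviance": [fits[k].deviance for k in _ROW_KEYS],
            "p_value": p_values,
        }
    )
    return ModelComparisonTable(frame=frame, best_model=_best_model(fits), fits=fits)


def _best_model(fits: dict[str, SubmodelFit]) -> str:
    """Smallest adequate model under the adjacent-line tests at 0.05."""

    def _p(reduced: str, full: str) -> float:
        r, f = fits[reduced], fits[full]
        return lrt(r.deviance, r.df_resid, f.deviance, f.df_resid)

    a = SIGNIFICANCE_LEVEL
    drift_needed = _p("age", "age-drift") <= a
    cohort_curv = _p("age-drift", "age-cohort") <= a
    period_curv = _p("age-drift", "age-period") <= a
    if cohort_curv and period_curv:
        return "Age-Period-Cohort"
    if cohort_curv:
        return "Age-Period-Cohort" if _p("age-cohort", "apc") <= a else "Age-Cohort"
    if period_curv:
        return "Age-Period-Cohort" if _p("age-period", "apc") <= a else "Age-Period"
    return "Age-drift" if drift_needed else "Age"
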