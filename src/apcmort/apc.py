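"""Age-period-cohort Poisson modelling with estimable functions.

The model for deaths D_ij with person-years N_ij on an I x J Lexis grid is

    ln E[D_ij] = ln N_ij + mu + alpha_i + beta_j + gamma_k,   k = j - i + I,

a Poisson GLM with log link and log person-years offset.  Because
cohort = period - age, the three linear trends are aliased and only
*estimable functions* are reported:

* the longitudinal age curve (age effects as followed within the
  reference cohort),
* the net drift, beta_L + gamma_L, the common linear time trend of the
  log rates (per 5-year step and annualized), and
* period and cohort *curvatures*: departures from linearity constrained
  to zero least-squares slope and to zero at the reference period
  (1995-1999 by default) and reference cohort (1945-1949 by default),
  reported as rate ratios with Wald confidence intervals.

Fitted cell means, curvatures and the drift are invariant to how the
aliased linear trend is allocated between period and cohort; the
``drift_scale`` flag only changes which margin carries the trend column,
for comparison with other software conventions.

Two parameterizations are available: ``factor`` (one level per
age/period/cohort category) and ``spline`` (natural cubic splines with a
configurable number of degrees of freedom per dimension, default 8).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import norm
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .rates import DEFAULT_AGE_STARTS, DEFAULT_PERIOD_STARTS, MortalityGrid

log = logging.getLogger(__name__)

_MODELS = ("age", "age-drift", "age-period", "age-cohort", "apc")


class IdentifiabilityError(ValueError):
    """Design matrix is rank deficient (aliased columns)."""


class ConvergenceError(RuntimeError):
    """Poisson likelihood maximization failed to converge."""


def cohort_index(i: int, j: int, I: int, J: int | None = None) -> int:
    """Diagonal (birth-cohort) index k = j - i + I for 1-based i, j.

    The oldest cohort (oldest age group in the first period) has k = 1;
    with I age groups and J periods there are K = I + J - 1 cohorts.
    """
    if not 1 <= i <= I:
        raise ValueError(f"age index i={i} outside 1..{I}")
    if j < 1 or (J is not None and j > J):
        raise ValueError(f"period index j={j} outside 1..{J}")
    return j - i + I


@dataclass
class APCDesign:
    """Grid layout, reference categories and parameterization of an APC fit.

    Cohorts are labelled by ``period_start - age_group_start`` (1900,
    1905, ..., 1995 in the default design); each label names the
    youngest 5-year birth band crossing that Lexis diagonal.
    """

    age_group_starts: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_AGE_STARTS))
    period_starts: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_PERIOD_STARTS))
    reference_period: int | None = None  # start year; default 1995 when present
    reference_cohort: int | None = None  # start year; default 1945 when present
    mode: str = "factor"  # "factor" | "spline"
    spline_df: tuple[int, int, int] = (8, 8, 8)  # (age, period, cohort)
    drift_scale: str = "cohort"  # "cohort" | "period"
    #: drop the first/last n Lexis diagonals from the likelihood.  The
    #: extreme cohorts sit in very few cells (the corners in a single
    #: one) and their factor-mode effects are unstable — a corner cell
    #: with zero deaths even sends the ML estimate to -inf.  Default 0:
    #: all cohorts retained.
    trim_cohorts: int = 0

    def __post_init__(self) -> None:
        self.age_group_starts = np.asarray(self.age_group_starts, dtype=int)
        self.period_starts = np.asarray(self.period_starts, dtype=int)
        for name, v in (("age_group_starts", self.age_group_starts),
                        ("period_starts", self.period_starts)):
            if len(v) < 2 or np.any(np.diff(v) != 5):
                raise ValueError(f"{name} must be 5-year spaced and increasing")
        if self.mode not in ("factor", "spline"):
            raise ValueError(f"unknown parameterization mode {self.mode!r}")
        if self.drift_scale not in ("cohort", "period"):
            raise ValueError(f"unknown drift_scale {self.drift_scale!r}")
        if self.reference_period is None:
            self.reference_period = 1995 if 1995 in self.period_starts else int(
                self.period_starts[len(self.period_starts) // 2]
            )
        if self.reference_cohort is None:
            self.reference_cohort = 1945 if 1945 in self.cohort_starts else int(
                self.cohort_starts[len(self.cohort_starts) // 2]
            )
        if self.reference_period not in self.period_starts:
            raise ValueError(f"reference period {self.reference_period} not on the grid")
        if self.reference_cohort not in self.cohort_starts:
            raise ValueError(f"reference cohort {self.reference_cohort} not on the grid")
        t = self.trim_cohorts
        if t < 0 or self.K - 2 * t < 3:
            raise ValueError(f"trim_cohorts={t} leaves fewer than 3 cohorts")
        if t >= min(self.I, self.J):
            raise ValueError(f"trim_cohorts={t} empties entire age or period levels")
        if not t <= self.ref_cohort_idx <= self.K - 1 - t:
            raise ValueError("reference cohort falls inside the trimmed diagonals")

    @property
    def I(self) -> int:  # noqa: E743 - conventional APC symbol
        return len(self.age_group_starts)

    @property
    def J(self) -> int:
        return len(self.period_starts)

    @property
    def K(self) -> int:
        return self.I + self.J - 1

    @property
    def cohort_starts(self) -> np.ndarray:
        first = int(self.period_starts[0]) - int(self.age_group_starts[-1])
        return first + 5 * np.arange(self.K)

    @property
    def ref_period_idx(self) -> int:
        return int(np.where(self.period_starts == self.reference_period)[0][0])

    @property
    def ref_cohort_idx(self) -> int:
        return int(np.where(self.cohort_starts == self.reference_cohort)[0][0])

    @property
    def retained_cohort_starts(self) -> np.ndarray:
        t = self.trim_cohorts
        return self.cohort_starts[t:self.K - t]

    def cell_indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """0-based (age, period, cohort) index per cell, cells in C order."""
        ii, jj = np.meshgrid(np.arange(self.I), np.arange(self.J), indexing="ij")
        ii, jj = ii.ravel(), jj.ravel()
        return ii, jj, jj - ii + self.I - 1

    def cell_mask(self) -> np.ndarray:
        """Boolean mask (raveled I x J) of cells inside the retained diagonals."""
        _, _, kk = self.cell_indices()
        t = self.trim_cohorts
        return (kk >= t) & (kk <= self.K - 1 - t)


def natural_spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis (truncated-power form) with ``df`` columns.

    Columns span {1, x} plus df - 2 curvature terms; knots sit at
    quantiles of the distinct x values.  Linear beyond the boundary
    knots, as a natural spline must be.
    """
    x = np.asarray(x, dtype=float)
    if df < 3:
        raise ValueError("natural spline needs df >= 3")
    ux = np.unique(x)
    if df > len(ux):
        raise ValueError(f"df={df} exceeds the {len(ux)} distinct support points")
    knots = np.quantile(ux, np.linspace(0.0, 1.0, df))

    def d(k: int) -> np.ndarray:
        return (
            np.clip(x - knots[k], 0.0, None) ** 3
            - np.clip(x - knots[-1], 0.0, None) ** 3
        ) / (knots[-1] - knots[k])

    cols = [np.ones_like(x), x]
    cols += [d(k) - d(df - 2) for k in range(df - 2)]
    return np.column_stack(cols)


def _level_basis(n_levels: int, mode: str, df: int) -> np.ndarray:
    """Per-level effect basis: identity (factor) or orthonormalized spline."""
    if mode == "factor" or df >= n_levels:
        return np.eye(n_levels)
    S = natural_spline_basis(np.arange(n_levels, dtype=float), df)
    Q, _ = np.linalg.qr(S)
    return Q


def _curvature_basis(S: np.ndarray, ref_idx: int) -> np.ndarray:
    """Restrict a level basis to curvatures: zero at ref, zero LS slope.

    Returns an (n_levels x (q - 2)) matrix whose columns all vanish at
    the reference level and have zero least-squares linear trend over
    the equally spaced level indices.
    """
    n = S.shape[0]
    xc = np.arange(n) - (n - 1) / 2.0
    C = np.vstack([S[ref_idx], xc @ S])
    nsp = linalg.null_space(C)
    if nsp.shape[1] != S.shape[1] - 2:
        raise IdentifiabilityError(
            "curvature constraints are degenerate for this basis"
        )
    return S @ nsp


@dataclass
class DesignInfo:
    """Assembled design matrix plus the pieces needed to read effects back."""

    X: np.ndarray
    names: list[str]
    terms: tuple[str, ...]
    slices: dict[str, slice]
    age_basis: np.ndarray
    period_curv_basis: np.ndarray | None
    cohort_curv_basis: np.ndarray | None
    cell_mask: np.ndarray  # raveled I x J; rows of X map to True cells


def build_design(design: APCDesign, terms: Sequence[str]) -> DesignInfo:
    """Design matrix for a (sub-)model on the grid's raveled cells.

    ``terms`` is a subset of {"age", "drift", "period", "cohort"}, where
    "period"/"cohort" mean the curvature-only blocks.  The age block
    always absorbs the intercept.  Cells on trimmed diagonals are
    excluded; the cohort block covers the retained levels only.
    """
    ii, jj, kk = design.cell_indices()
    mask = design.cell_mask()
    ii, jj, kk = ii[mask], jj[mask], kk[mask]
    trim = design.trim_cohorts
    n_coh = design.K - 2 * trim
    cols: list[np.ndarray] = []
    names: list[str] = []
    slices: dict[str, slice] = {}
    Sa = _level_basis(design.I, design.mode, design.spline_df[0])
    Bp = Bc = None

    def add(block: np.ndarray, block_names: list[str], key: str) -> None:
        start = sum(c.shape[1] for c in cols)
        cols.append(block)
        names.extend(block_names)
        slices[key] = slice(start, start + block.shape[1])

    if "age" not in terms:
        raise ValueError("every model includes the age term")
    if design.mode == "factor":
        age_names = [f"age:{a}" for a in design.age_group_starts]
    else:
        age_names = [f"age:b{m + 1}" for m in range(Sa.shape[1])]
    add(Sa[ii], age_names, "age")
    if "drift" in terms:
        if design.drift_scale == "cohort":
            x = (kk - design.ref_cohort_idx).astype(float)
        else:
            x = (jj - design.ref_period_idx).astype(float)
        add(x[:, None], ["drift"], "drift")
    if "period" in terms:
        Sp = _level_basis(design.J, design.mode, design.spline_df[1])
        Bp = _curvature_basis(Sp, design.ref_period_idx)
        add(Bp[jj], [f"per:c{m + 1}" for m in range(Bp.shape[1])], "period")
    if "cohort" in terms:
        Sc = _level_basis(n_coh, design.mode, design.spline_df[2])
        Bc = _curvature_basis(Sc, design.ref_cohort_idx - trim)
        add(Bc[kk - trim], [f"coh:c{m + 1}" for m in range(Bc.shape[1])], "cohort")
    return DesignInfo(
        X=np.hstack(cols),
        names=names,
        terms=tuple(terms),
        slices=slices,
        age_basis=Sa,
        period_curv_basis=Bp,
        cohort_curv_basis=Bc,
        cell_mask=mask,
    )


@dataclass
class PoissonFitResult:
    """Maximum-likelihood Poisson GLM fit (log link, log-exposure offset)."""

    coef: np.ndarray
    cov: np.ndarray
    deviance: float
    df_resid: int
    fitted: np.ndarray  # fitted means, raveled
    names: list[str]
    converged: bool


def _poisson_deviance(d: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(d > 0, d * np.log(d / mu), 0.0)
    return float(2.0 * np.sum(term - (d - mu)))


def fit_poisson(
    X: np.ndarray,
    deaths: np.ndarray,
    person_years: np.ndarray,
    names: Sequence[str] | None = None,
    maxiter: int = 100,
) -> PoissonFitResult:
    """Fit a Poisson GLM with log link and offset ln(person_years).

    Real-valued death counts are allowed (corrected counts).  The IRLS
    solution is polished with explicit Newton steps until the score is
    at numerical noise level, so downstream invariance contracts hold to
    ~1e-10.  Rank-deficient designs raise :class:`IdentifiabilityError`
    naming the aliased columns.
    """
    d = np.asarray(deaths, dtype=float).ravel()
    n_py = np.asarray(person_years, dtype=float).ravel()
    if np.any(n_py <= 0):
        raise ValueError("person_years must be positive in every cell")
    off = np.log(n_py)
    X = np.asarray(X, dtype=float)
    names = list(names) if names is not None else [f"x{m}" for m in range(X.shape[1])]

    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > max(X.shape) * np.finfo(float).eps * diag.max()))
    if rank < X.shape[1]:
        aliased = [names[p] for p in piv[rank:]]
        raise IdentifiabilityError(
            f"design matrix is rank deficient; aliased columns: {aliased}"
        )

    glm = sm.GLM(d, X, family=sm.families.Poisson(), offset=off)
    with warnings.catch_warnings():
        # exact-expectation inputs (deviance ~ 0) trip this benign warning
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = glm.fit(maxiter=maxiter, tol=1e-10)
    beta = np.asarray(res.params, dtype=float)

    # Newton polish to machine-precision score
    scale = 1.0 + d.sum()
    dev = np.inf
    for _ in range(50):
        eta = off + X @ beta
        mu = np.exp(eta)
        g = X.T @ (d - mu)
        if np.max(np.abs(g)) <= 1e-11 * scale:
            break
        H = (X * mu[:, None]).T @ X
        step = np.linalg.solve(H, g)
        new_dev = _poisson_deviance(d, np.exp(off + X @ (beta + step)))
        shrink = 0
        while new_dev > dev + 1e-12 * scale and shrink < 30:
            step *= 0.5
            new_dev = _poisson_deviance(d, np.exp(off + X @ (beta + step)))
            shrink += 1
        beta = beta + step
        dev = new_dev
    eta = off + X @ beta
    mu = np.exp(eta)
    g = X.T @ (d - mu)
    if np.max(np.abs(g)) > 1e-7 * scale:
        raise ConvergenceError(
            f"score not converged (max |score| = {np.max(np.abs(g)):.3g})"
        )
    H = (X * mu[:, None]).T @ X
    if np.linalg.cond(H) > 1e10:
        log.warning(
            "information matrix is nearly singular (weakly identified effects, "
            "typically thin cohort diagonals with zero counts); consider "
            "mode='spline' or trim_cohorts>0"
        )
    cov = np.linalg.inv(H)
    return PoissonFitResult(
        coef=beta,
        cov=cov,
        deviance=_poisson_deviance(d, mu),
        df_resid=len(d) - X.shape[1],
        fitted=mu,
        names=names,
        converged=True,
    )


_MODEL_TERMS = {
    "age": ("age",),
    "age-drift": ("age", "drift"),
    "age-period": ("age", "drift", "period"),
    "age-cohort": ("age", "drift", "cohort"),
    "apc": ("age", "drift", "period", "cohort"),
}


@dataclass
class SubmodelFit:
    """One fitted APC sub-model (age, age-drift, age-period, ...)."""

    model: str
    design: APCDesign
    info: DesignInfo
    result: PoissonFitResult

    @property
    def deviance(self) -> float:
        return self.result.deviance

    @property
    def df_resid(self) -> int:
        return self.result.df_resid

    @property
    def drift_per_period(self) -> float:
        if "drift" not in self.info.slices:
            raise ValueError(f"model {self.model!r} has no drift term")
        return float(self.result.coef[self.info.slices["drift"]][0])

    @property
    def drift_se(self) -> float:
        if "drift" not in self.info.slices:
            raise ValueError(f"model {self.model!r} has no drift term")
        m = self.info.slices["drift"].start
        return float(np.sqrt(self.result.cov[m, m]))


def fit_submodel(grid: MortalityGrid, design: APCDesign, model: str) -> SubmodelFit:
    """Fit one of the sequential sub-models by name."""
    if model not in _MODEL_TERMS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_MODEL_TERMS)}")
    _check_grid(grid, design)
    info = build_design(design, _MODEL_TERMS[model])
    result = fit_poisson(
        info.X,
        grid.deaths.ravel()[info.cell_mask],
        grid.person_years.ravel()[info.cell_mask],
        names=info.names,
    )
    return SubmodelFit(model=model, design=design, info=info, result=result)


def _check_grid(grid: MortalityGrid, design: APCDesign) -> None:
    if grid.deaths.shape != (design.I, design.J):
        raise ValueError(
            f"grid shape {grid.deaths.shape} does not match design "
            f"({design.I}, {design.J})"
        )


def rr_with_ci(
    coef: np.ndarray | float, se: np.ndarray | float, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rate ratio exp(coef) with Wald interval exp(coef -+ z * se)."""
    coef = np.asarray(coef, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se < 0):
        raise ValueError("standard errors must be non-negative")
    z = norm.ppf(0.5 + level / 2.0)
    with np.errstate(over="ignore"):  # huge se -> inf bound, reported as such
        return np.exp(coef), np.exp(coef - z * se), np.exp(coef + z * se)


@dataclass
class DriftEstimate:
    """Net drift: common linear trend of the log rates."""

    per_period: float  # per 5-year step, log scale
    se_per_period: float
    level: float = 0.95

    @property
    def annual(self) -> float:
        return self.per_period / 5.0

    @property
    def annual_pct(self) -> float:
        """Annual percent change of the rates implied by the drift."""
        return 100.0 * (np.exp(self.annual) - 1.0)

    def ci_per_period(self) -> tuple[float, float]:
        z = norm.ppf(0.5 + self.level / 2.0)
        return (self.per_period - z * self.se_per_period,
                self.per_period + z * self.se_per_period)

    def ci_annual(self) -> tuple[float, float]:
        lo, hi = self.ci_per_period()
        return lo / 5.0, hi / 5.0


@dataclass
class APCFit:
    """Full APC fit reported through Holford estimable functions."""

    design: APCDesign
    result: PoissonFitResult
    info: DesignInfo
    age_curve: pd.DataFrame      # age_group_start, log_rate, se, rate_per_100k
    period_effects: pd.DataFrame  # period_start, log_rr, se, rr, rr_lo, rr_hi
    cohort_effects: pd.DataFrame  # cohort_start, log_rr, se, rr, rr_lo, rr_hi
    drift_per_period: float
    drift_se: float
    longitudinal_age_slope: float  # per 5-year step of age, log scale

    @property
    def deviance(self) -> float:
        return self.result.deviance

    @property
    def df_resid(self) -> int:
        return self.result.df_resid

    @property
    def fitted(self) -> np.ndarray:
        """Fitted cell means (I x J); trimmed cells, if any, are NaN."""
        out = np.full(self.design.I * self.design.J, np.nan)
        out[self.info.cell_mask] = self.result.fitted
        return out.reshape(self.design.I, self.design.J)

    def drift(self) -> DriftEstimate:
        return DriftEstimate(self.drift_per_period, self.drift_se)

    def to_dict(self) -> dict:
        d = self.drift()
        lo5, hi5 = d.ci_per_period()
        return {
            "design": {
                "age_group_starts": self.design.age_group_starts.tolist(),
                "period_starts": self.design.period_starts.tolist(),
                "cohort_starts": self.design.cohort_starts.tolist(),
                "reference_period": int(self.design.reference_period),
                "reference_cohort": int(self.design.reference_cohort),
                "mode": self.design.mode,
                "drift_scale": self.design.drift_scale,
            },
            "deviance": self.deviance,
            "df_resid": self.df_resid,
            "drift": {
                "per_period": d.per_period,
                "se_per_period": d.se_per_period,
                "ci_per_period": [lo5, hi5],
                "annual": d.annual,
                "annual_pct": d.annual_pct,
            },
            "longitudinal_age_slope_per_period": self.longitudinal_age_slope,
            "age_curve": self.age_curve.to_dict(orient="list"),
            "period_effects": self.period_effects.to_dict(orient="list"),
            "cohort_effects": self.cohort_effects.to_dict(orient="list"),
        }


def _effect_frame(
    labels: np.ndarray, basis: np.ndarray, coef: np.ndarray, cov: np.ndarray,
    label_name: str, level: float = 0.95,
) -> pd.DataFrame:
    eff = basis @ coef
    var = np.einsum("ij,jk,ik->i", basis, cov, basis)
    se = np.sqrt(np.clip(var, 0.0, None))
    rr, lo, hi = rr_with_ci(eff, se, level=level)
    return pd.DataFrame(
        {label_name: labels, "log_rr": eff, "se": se, "rr": rr, "rr_lo": lo, "rr_hi": hi}
    )


def _ls_slope(values: np.ndarray) -> float:
    x = np.arange(len(values)) - (len(values) - 1) / 2.0
    return float(x @ values / (x @ x))


def fit_apc(grid: MortalityGrid, design: APCDesign | None = None) -> APCFit:
    """Fit the full APC model and report its estimable functions.

    The predictor is parameterized as

        longitudinal age curve + drift + period curvature + cohort curvature

    with both curvatures zero at their reference category and of zero
    least-squares slope, so the reference rate ratios are exactly 1.
    """
    if design is None:
        design = APCDesign(
            age_group_starts=grid.age_group_starts, period_starts=grid.period_starts
        )
    _check_grid(grid, design)
    info = build_design(design, _MODEL_TERMS["apc"])
    res = fit_poisson(
        info.X,
        grid.deaths.ravel()[info.cell_mask],
        grid.person_years.ravel()[info.cell_mask],
        names=info.names,
    )

    sl = info.slices
    age_coef = res.coef[sl["age"]]
    age_cov = res.cov[sl["age"], sl["age"]]
    A = info.age_basis @ age_coef
    age_var = np.einsum("ij,jk,ik->i", info.age_basis, age_cov, info.age_basis)
    age_curve = pd.DataFrame(
        {
            "age_group_start": design.age_group_starts,
            "log_rate": A,
            "se": np.sqrt(np.clip(age_var, 0.0, None)),
            "rate_per_100k": 1e5 * np.exp(A),
        }
    )

    period_effects = _effect_frame(
        design.period_starts, info.period_curv_basis,
        res.coef[sl["period"]], res.cov[sl["period"], sl["period"]], "period_start",
    )
    cohort_effects = _effect_frame(
        design.retained_cohort_starts, info.cohort_curv_basis,
        res.coef[sl["cohort"]], res.cov[sl["cohort"], sl["cohort"]], "cohort_start",
    )

    m = sl["drift"].start
    drift = float(res.coef[m])
    drift_se = float(np.sqrt(res.cov[m, m]))
    # Slope of log rate within a cohort per 5-year age step (alpha_L + beta_L):
    # the age block carries it when drift sits on the cohort scale, and
    # needs the drift added back when drift sits on the period scale.
    long_slope = _ls_slope(A) + (drift if design.drift_scale == "period" else 0.0)

    return APCFit(
        design=design,
        result=res,
        info=info,
        age_curve=age_curve,
        period_effects=period_effects,
        cohort_effects=cohort_effects,
        drift_per_period=drift,
        drift_se=drift_se,
        longitudinal_age_slope=long_slope,
    )


def extract_drift(fit: APCFit | SubmodelFit) -> DriftEstimate:
    """Net drift (per 5-year step and annualized) from a fitted model."""
    if isinstance(fit, APCFit):
        return fit.drift()
    return DriftEstimate(fit.drift_per_period, fit.drift_se)
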