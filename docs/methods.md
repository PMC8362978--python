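# Methods

## Problem and model

Registry mortality series from settings with historically weak vital
statistics — here modelled on female breast-cancer deaths in the states of
north-east Brazil, 1980–2019 — cannot be analysed as recorded: a material
share of deaths is coded to the symptoms/ill-defined ICD chapter or to
unspecified cancer sites, and a further share is never registered at all,
with all three defects improving over calendar time.  Ignoring them biases
both the level and the *trend* of cause-specific mortality.  The package
therefore chains three components: a count correction, rate computation, and
an age–period–cohort (APC) Poisson model, plus a synthetic registry that
provides ground truth for testing all of them.

Deaths D_ij and person-years N_ij live on an I × J Lexis grid of 5-year age
groups and 5-year periods (default I = 13, ages 20–24 … 80+; J = 8,
1980–1984 … 2015–2019).  Cells on the same diagonal share a birth cohort,
k = j − i + I, giving K = I + J − 1 = 20 cohorts labelled by
period start − age start (1900, 1905, …, 1995).  Each label names the
youngest 5-year birth band crossing that diagonal (a 5 × 5 cell actually
mixes two adjacent bands); the oldest and youngest diagonals intersect the
grid in very few cells — the corners in exactly one.

The model is a Poisson GLM with log link and offset ln N_ij:

    ln E[D_ij] = ln N_ij + μ + α_i + β_j + γ_k.

Because k = j − i + const, the decomposition of the linear trend among age,
period and cohort is not identified: adding c·j to the period effects and
subtracting c·k from the cohort effects (with compensating age and intercept
shifts) changes no fitted mean.  Following the estimable-function approach,
the fit is parameterized directly in identifiable terms:

* a **longitudinal age curve** A_i (absorbing the intercept),
* a single **net drift** δ = β_L + γ_L per 5-year step, carried by the
  centred cohort index by default (`drift_scale="cohort"`, which makes A_i
  the age curve as followed within the reference cohort; the
  `"period"` allocation yields the cross-sectional curve instead and is
  provided for comparison with other software conventions),
* **period and cohort curvatures**: effect vectors constrained to zero
  least-squares slope over their level indices and to zero at the reference
  level, so the reference rate ratios are exactly 1.

Counting parameters: I + 1 + (J − 2) + (K − 2) = I + J + K − 3, the rank of
the unconstrained APC design, so the constrained design is full rank and no
generalized inverse is needed.  Curvatures, drift, fitted means and
deviances are invariant to the trend allocation; this is asserted by tests
at 1e-8 relative tolerance.  The longitudinal age slope (α_L + β_L) is
reported as the least-squares slope of the longitudinal age curve.

References default to the 1995–1999 period and the 1945–1949 cohort —
central categories, which are better supported than the extremes.

### Parameterizations and thin diagonals

`mode="factor"` gives one parameter per category; `mode="spline"` replaces
each categorical basis with a natural cubic spline (truncated-power basis,
knots at quantiles of the level indices, default 8 df per dimension, so the
sub-model ladder has residual df 96/95/89/83/89/95 on the default grid,
versus 91/90/72/66/84/90 for the factor ladder).  The spline basis is
orthonormalized before the curvature constraints are imposed; constraints
are applied by restriction to the null space of the (value-at-reference,
linear-trend) functionals, so they hold exactly in either mode.

Factor-mode effects for the extreme cohorts rest on one or two cells.  If a
corner cell records zero deaths, its cohort's ML effect diverges to −∞ and
the information matrix becomes numerically singular — the fit then emits a
warning.  Remedies, in preferred order: the spline mode (which ties extreme
cohorts to their neighbours), or `trim_cohorts=t` to exclude the first and
last t diagonals from the likelihood (trimmed cells appear as NaN fitted
values).  All cohorts are retained by default.

### Numerical details

Fits run through statsmodels' IRLS (tolerance 1e-10, 100 iterations) and are
then polished with explicit damped Newton steps until the score is below
1e-11·(1 + ΣD), i.e. at numerical noise; a fit whose score stays above
1e-7·(1 + ΣD) raises an error.  The covariance is the inverse observed
information at the optimum (equal to the expected information for the
canonical link).  Deviance is 2Σ[D ln(D/μ̂) − (D − μ̂)] with 0·ln 0 = 0;
real-valued (corrected) counts are accepted throughout.  Rank deficiency is
detected by pivoted QR before fitting and reported with the aliased column
names.  Confidence intervals are Wald on the log scale (z = 1.959964 at
95%); a weakly identified effect can legitimately report an infinite upper
bound.  Likelihood-ratio p-values use the upper tail of χ² with the residual-df
difference; a deviance difference below −1e-8 raises a nesting error, and a
zero-df comparison reports NA.

## Record correction

Cause classes partition valid ICD-9/ICD-10 codes (truncated to 3-character
roots): breast (174 / C50); incomplete cancer diagnosis (195–199 /
C76, C77, C78, C79, C80, C97); ill-defined (780–799 / R00–R99); non-natural
(ICD-9 E-codes and 800–999, ICD-10 chapters S, T, V–Y); other defined cancer
(remaining 140–208 / C00–C97, D00–D48); everything else is other defined
natural.  The four steps:

1. A fraction (default 0.5) of each stratum's ill-defined deaths is
   redistributed proportionally over the defined natural classes (breast,
   other cancer, other natural) — external causes receive nothing and the
   stratum total is conserved.  Strata default to unit × year × age group so
   redistribution cannot move deaths across the Lexis surface; a coarser
   unit-level stratification is available for sensitivity analyses.
2. Incomplete-diagnosis deaths are redistributed over the specified cancers
   within unit × year × age group strata.
3. The breast shares of steps 1 and 2 — both computed from the *original*
   registered counts, so the two corrections do not compound — are added to
   the registered breast count.
4. The sum is multiplied by a decade-specific completeness factor (≥ 1).

Counts stay real-valued; any rounding is left to report time.  A stratum
holding garbage deaths but no eligible receiving class keeps those deaths in
place with a logged warning rather than failing — the robust choice for
small cells.  The record-level and pre-tabulated input paths share one
implementation, and their equivalence is a tested property.  Completeness
factors are user-supplied configuration (published state-level estimates
exist but are not bundled); the demo uses the inverses of the synthetic
generator's completeness values.

## Rates

Age-specific rates are scale·D/N (default per 100,000).  Direct
standardization uses Σwᵢrᵢ/Σwᵢ with the Segi world standard in the Doll–Hill
modification, restricted to ages 20+ with the open 80+ interval carrying
weight 1000; the weights ship as a CSV data file and any alternative
standard can be supplied.  Truncated rates pool deaths and person-years at
or above a group boundary.  Truncated and standardized rates are computed
per 5-year period (the analysis resolution); period averages can be taken
as simple or person-year-weighted means of the quinquennial values —
both are elementary on the returned tables and neither is canonical here.

## Synthetic registry

The generator draws breast deaths per cell as Poisson(N_ij·rate_ij) with
rate_ij = exp(μ + α_i + β_j + γ_k) and known effect vectors, then surrounds
them with the rest of a plausible female death registry: cause-mix fractions
give the shares of other cancers (0.12) and other natural causes (0.85) in
total natural deaths — implying a 3% breast share, in line with an adult
female population — plus external deaths at 0.10 of the natural total.
Corruption is applied in registry order: cancer deaths become incomplete
diagnoses with probability 0.06, natural deaths become ill-defined with
probability 0.12, and finally each death is registered with its decade's
completeness (0.80/0.85/0.93/0.98 for the 1980s–2010s).  The garbage-code
probabilities and completeness schedule are free parameters chosen once as
plausible for the region's registry history; no published per-state shares
are bundled.

Default generating effects mimic the study setting: an age curve rising from
0.6 to 85 deaths per 100,000 with a mid-life deceleration, a shallow period
V-shape turning upward after 2000, and cohort risk increasing for women born
after the late 1940s with a flattening in the youngest diagonals.  Deaths
are placed at 5-year-cell resolution by default (`per_year=True`
disaggregates years uniformly); ages are recorded as the group's start year.
Each run uses one `numpy.random.Generator` seeded from the config — no
global state, and identical configs are byte-identical.

What the generator does *not* emulate: certification chains and associated
causes (underlying cause only), cell-to-cell population structure (constant
person-years per cell), migration, digit preference in ages, and
revision-change artefacts beyond the 1996 ICD-9→ICD-10 switch in code
labels.  Passing tests therefore demonstrate the correctness of the
arithmetic and the estimators under a clean APC data-generating process, not
robustness to every real-registry pathology.

## Design choices

* Step-1 redistribution strata: within-cell by default (coarse unit-level
  mode available) — moving ill-defined deaths across ages or years would
  distort the Lexis surface being modelled.
* Parallel shares in steps 1–2 (both from registered counts), matching the
  "sum of the values obtained in the previous steps" structure of the
  correction.
* The incomplete-diagnosis code set is the deduplicated
  {195–199, C76–C80, C97}.
* The best-model rule in the comparison ladder: the smallest model the
  adjacent-line tests at 0.05 fail to reject in favour of a larger one,
  reported alongside the full table.
* When the cohort term is not supported, the drift (and its CI) from the
  age-drift model is the natural summary of generational change; the
  package exposes that fit directly.

## Problem sizes in the tests

The suite favours exact-expectation inputs (deviance ≈ 0) for sharp
tolerances (1e-6 and better), 10⁶ person-years per cell and 50 seeds for the
drift-coverage study, 4 × 3 grids for brute-force likelihood oracles, and
2 × 10⁴–2 × 10⁶ person-years for record-level round trips — sizes chosen so
each check is decisive for the property it tests while the whole suite runs
in well under a minute per module.

## Known limitations

* The APC identification problem is handled by estimable functions, not
  solved: any statement about the *level* of period vs cohort effects
  depends on the reference choices and drift allocation.
* Factor-mode extreme-cohort effects are unstable by construction (one or
  two supporting cells); use the spline mode or trimming when they matter.
* Completeness correction multiplies counts but not their sampling
  variance; standard errors after large corrections are optimistic.
* The correction assumes garbage codes distribute proportionally to
  registered specified causes within a stratum — untestable from the
  registry itself.
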