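# Demo pipeline configuration: one synthetic state, 1980-2019, 13 age
# groups (20-24 ... 80+), 8 quinquennia.  Correction factors are the
# inverses of the generator's registration completeness by decade.
seed: 1
unit: SYN
outdir: apcmort-demo
reference_period: 1995
reference_cohort: 1945
correction_fraction: 0.5
correction_factors:
  1980: 1.25
  1990: 1.1764705882352942
  2000: 1.0752688172043012
  2010: 1.0204081632653061
# smoothed parameterization: robust to the thin corner cohorts of the
# Lexis grid (a factor-mode corner cohort with zero deaths is unstable)
mode: spline
synthetic:
  population_base: 200000.0
  p_ill_defined: 0.12
  p_incomplete: 0.06
  completeness:
    1980: 0.80
    1990: 0.85
    2000: 0.93
    2010: 0.98
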