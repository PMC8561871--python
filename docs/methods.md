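# Methods

This note records the models and procedures `bioage` implements, the
defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the numerical decisions a maintainer
would otherwise have to reverse-engineer.

## Growth references and the LMS percentile engine

A reference distribution for height or BMI at each age and sex is
summarised by the Box-Cox power `L`, median `M` and coefficient of
variation `S`; a measurement `x` has z-score
`((x/M)^L − 1)/(L·S)`, or `ln(x/M)/S` when `|L| < 1e-7` (the continuous
limit of the Box-Cox family). Percentiles are `100·Φ(z)`. The inverse
transform refuses z-scores outside the distribution's support
(`1 + L·S·z ≤ 0`).

`L`, `M`, `S` are linearly interpolated on the age grid; reference
tables are dense enough (half-year steps here, monthly in the licensed
originals) that higher-order interpolation changes nothing testable.
Queries outside the tabulated age span raise rather than extrapolate.
An optional month-binning mode snaps the matching age to the nearest
whole month before lookup, for compatibility with references tabulated
by month; the default is continuous interpolation.

The percent-of-adult-height curve is `100·M_height(age)/A` with `A` the
mean adult (18+) stature — 177.6 cm for males and 163.7 cm for females
by default. Its inverse (biological age at a given percent) uses
monotone linear interpolation; a percent lying on a flat segment of the
curve maps to the youngest age of the segment, a deterministic choice
that is conservative toward later maturity.

### Synthetic reference tables

The licensed British reference tables and published adult-height
prediction coefficients are not redistributable, so
`bioage.synthetic_reference` builds synthetic stand-ins: monotone
(PCHIP) curves through anchor values of typical magnitude for UK
children, ages 6-20. The girls' curve attains exactly 91.5% of the
163.7 cm adult mean at age 12 — the anchor used throughout the tests —
and both sexes reach the adult mean at 18. Height uses `L = 1` with a
CV peaking mid-puberty (0.048 at the pubertal peak age, 12 for girls
and 14 for boys); BMI uses `L` of −1.4/−1.3 (girls/boys) and a CV
rising from 0.10-0.105 at age 6 by 0.0025 per year. The coefficient
table's stature weight rises with age (0.45 at age 6, capped at 0.95),
the weight term is a small negative correction (−0.02 cm/kg) and the
mid-parent term is 0.30; intercepts are solved per age so that a
reference-median child with mid-parent height at the adult mean is
predicted exactly to the adult mean. Real tables can be supplied as
CSV (`GrowthReference.from_csv`, `KRCoefficientTable.from_csv`) and
every pipeline entry point accepts them.

## Maturity assessment

Mid-parent height is the arithmetic mean of the two parents' statures;
children missing either parent's height are complete-case excluded
with a logged reason. Predicted adult height below current stature is
possible for extreme inputs of a linear predictor and is logged, not
rejected; percent attained above 100 is capped at 100 with a warning
(common just before full maturity, where prediction error dominates
the shrinking residual growth). Timing uses the ±1-year offset rule
with the boundary included: an offset of exactly +1.0 year is early,
−1.0 late.

## Weight classification

Percentile cut-offs are closed below and open above: <2 underweight,
[2, 85) healthy, [85, 95) overweight, ≥95 obese. Underweight screening
uses the chronological classification at the first visit (screening
precedes adjustment); children who fall to underweight only under the
biological matching stay in the modelling set and remain visible in the
descriptive tables. The biological matching age is the continuous
inverse-lookup biological age unless month-binning is enabled. At the
second visit, where most adolescents are at or near full maturity, a
percent attained above the reference maximum is clamped to the oldest
reference age instead of raising, so late-adolescent visits are not
dropped.

## Cardiometabolic risk

Blood pressure is the mean of two successive readings; MAP is
`(SBP + 2·DBP)/3`. The composite score sums within-sample z-scores of
reciprocal HDL, LDL, fasting glucose and MAP. The reciprocal is taken
*before* standardisation — the reciprocal of a z-score is undefined at
zero and reverses ordering incoherently — so every component points in
the higher-is-worse direction. Z-scores use the sample SD (n−1),
computed over the modelling sample after exclusions; a sex-stratified
mode is available behind a flag (pooled is the default). The median
split assigns ties to "low". The score is sample-specific by
construction and carries no clinical cut-point.

## Regression models and comparison

Outcomes — the age-17 BMI category (underweight, a handful of cases,
merged into healthy) and the high/low CMR class — are modelled by
maximum-likelihood multinomial logit with the healthy/low level as
reference. The age-11 BMI category enters as an ordinal score
(healthy 0, overweight 1, obese 2), a single slope rather than
dummies, matching the single per-category-step odds ratio the design
reports. Covariates are sex, ethnicity (white/non-white) and a 4-level
maternal socio-economic group. Both schemes are fit to the *same*
outcome (the chronological age-17 category) on the same sample, so
their AIC/BIC are directly comparable; |ΔBIC| < 2 is read as
equivalent, otherwise the lower-BIC model is meaningfully better.

Numerics: Newton's method (falling back to L-BFGS for ill-conditioned
Hessians), max 200 iterations; non-convergence raises an explicit
error rather than returning silent output, and an interaction model
with structurally empty cells is reported as inestimable instead of
aborting the pipeline run. With ungrouped data the saturated
log-likelihood is zero, so deviance is taken as −2·lnL and the
residual df as `n·(J−1) − k`; the dispersion `φ = deviance/df` scales
standard errors (and hence confidence intervals) by `√φ` but never
touches coefficients or the information criteria. This definition is
stated because deviance-scaling semantics for multinomial models vary
between packages; note that for ungrouped data φ is a fit summary, not
a sharp overdispersion test. `k` counts every estimated parameter,
intercepts included, and BIC uses `n` = children in the modelling
sample.

Transition tables cross-tabulate each scheme's categories at the two
visits; the Pearson chi-square uses `(r−1)(c−1)` df. Early-maturer
odds ratios are 2×2 contingency ratios (early vs. not × outcome) with
Woolf intervals and a 0.5 continuity correction when a cell is empty.
Interaction models add timing × BMI-category and timing × sex terms to
the adjusted-category model and drop ethnicity and SES for parsimony.

## The synthetic cohort generator

The generator emulates a two-visit British birth-cohort subsample:
n = 1525, 51.6% girls, visit ages 11.75 (SD 0.20) and 17.71 (SD 0.36)
years, 98% white, four maternal SES groups (49% in the two manual /
junior grades), parents drawn around the adult norms with SD 6.5 cm
(a typical adult stature SD).

**Maturity offsets.** Per-sex early/on-time/late shares — 8/90/2% for
boys, 32/63/5% for girls — are inverted to a normal offset law by
matching the two tail probabilities at ±1 year (boys
μ ≈ 0.19, σ ≈ 0.58; girls μ ≈ 0.56, σ ≈ 0.95). An optional override
draws offsets as N(0, sd), including the degenerate sd = 0 case in
which every child is exactly on time and the two classification
schemes coincide.

**Pipeline consistency.** Visit-1 height is solved (fixed point, the
weight term is a small contraction) so that the prediction equation
reads back exactly the latent percent of adult height
`p_ref(age + offset)`; true adult height is then `100·h/percent`. With
measurement noise at zero the pipeline therefore recovers every
child's latent biological age up to interpolation error — by design,
so latent-truth recovery tests are exact. The flip side is that the
real prediction method's shrinkage (systematic over-prediction of
adult height for early maturers) is *not* emulated; passing recovery
tests say nothing about that error source in real data.

**Adiposity and the two inflation channels.** A latent adiposity
z-score (mean ≈ 0.10, SD ≈ 1.10, solved from the target biological-
basis prevalences 2/78/12/8%) carries a 0.10 correlation with the
maturity offset. Early maturers' excess BMI at the first visit then
has two parts, mirroring the observed pattern that the unadjusted
early-maturer odds ratio (~3.7) falls only partway (toward ~2-3) after
adjustment: a *real* transient pubertal elevation of 0.65 kg/m² per
year of offset, visible under both matching schemes and absent by the
second visit; and the *matching artifact* — BMI is placed on the
reference at the biological age, so the chronological percentile is
inflated for early maturers while the biological percentile recovers
the latent z exactly. Setting `bmi_inflation_per_year = 0` switches
the artifact off (BMI is placed at the chronological age); a positive
value replaces the reference-consistent artifact with a flat kg/m² per
year term. Visit-2 adiposity tracks visit 1 with correlation 0.78 and
is placed at the chronological age (maturity differences in BMI have
largely washed out by 17.7).

**Cardiometabolic panel.** A latent risk index
`0.9·(category at 17) + 1.1·(male) + 0.35·(early) + N(0,1)` feeds
glucose, HDL (negatively), LDL and true blood pressures with fixed
loadings and noise; two readings per pressure add 3 mmHg of
measurement error. These effect sizes were calibrated once, against
large-sample simulation, to the descriptive anchors of the emulated
cohort (composite score means of about +0.6 in boys and −0.6 in girls,
SD ≈ 2.3, boys at roughly twice the odds of high risk) and then
frozen.

**What the generator does not emulate.** Attrition and selection
bias; more than two visits and growth-curve dynamics between them;
prediction-method shrinkage (above); ethnic heterogeneity beyond a
binary marginal; seasonal or secular trends in the references. Tests
passing on this generator demonstrate the pipeline's internal
consistency and statistical behaviour under known truth, not the
field validity of the maturity adjustment.

## Known limitations

- With the generator's effect sizes at their calibrated defaults, the
  two schemes are *not* statistically equivalent for the CMR outcome
  under the no-inflation null: the biological matching distortion is
  pure noise there, so the chronological model is slightly but
  systematically better (mean ΔBIC ≈ +1.8 at n ≈ 1500) and replicate
  ΔBIC values scatter well beyond ±2. Equivalence-in-most-replicates
  would require a weaker category-risk association than the calibrated
  one.
- The dispersion estimate from ungrouped multinomial deviance is a
  descriptive scale factor, not a formal overdispersion test.
- The synthetic references are magnitude-realistic but not the
  licensed tables; absolute percentiles from them should not be
  quoted for real children.
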