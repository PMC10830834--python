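# Methods

This note documents the statistical models, the synthetic data that
exercises them, the numerical choices, and the known limits of what the
package's validation demonstrates.

## Two-stage analysis

Historical trials differ in design and error variance, so yields are not
pooled directly. Stage 1 fits each trial year separately: genotype fixed
(cell-means coding, so a BLUE and SE fall out per genotype), days to
flowering (DTF) as a fixed covariate centred within year, and season plus
the design's blocking factors as IID random effects. Blocking-factor labels
are made unique per trial (season × location) before fitting, so "rep 1" in
two different trials never shares a level. The BLUE for a genotype is its
adjusted mean at the year-mean DTF with other fixed factors averaged;
weights are 1/SE².

Stage 2 stacks all genotype-year BLUEs: year fixed, genotype random with
covariance σ²g·A (or σ²g·I without a pedigree), residual covariance
σ²ε·diag(1/w). Weights enter as *known* residual precisions — the
inverse-squared-SE weighting scheme — so stage-2's σ²ε is a dimensionless
calibration factor (≈ 1 when stage-1 SEs are well calibrated). Breeding
values are reported on the phenotypic scale (mean fitted year level plus
the genotype prediction) so thresholds in kg/ha are meaningful; genotype
*deviations* and PEVs are invariant to that shift.

Season enters stage 1 as random by default; a `season_role="fixed"` switch
exists because either convention is defensible for two seasons per year.
Whether stage 2 should pool one BLUE per genotype-year (season absorbed in
stage 1, the default here) or per genotype-year-season is a genuine
ambiguity for two-season programs; one-per-year was chosen as the variant
consistent with extracting "BLUEs per year".

## REML engine

Variance components maximise the residual log-likelihood

-2ℓ_R = log|R| + log|G| + log|C| + y'Py (+ const),

evaluated through the Cholesky factor of the MME coefficient matrix C —
no n×n inversions during optimisation. The optimiser is L-BFGS-B on
log-variances (bounds keep components positive; components finishing at
the floor 1e-8 × var(y) are clamped and flagged), started deterministically
from the OLS residual variance split evenly across components. Numeric
gradients leave ~1e-6 relative slack along flat directions of the
log-likelihood, so on small problems (coefficient matrix ≤ 400) a
Nelder–Mead polish (xatol 1e-8) tightens the optimum; large problems don't
need that precision and skip it. PEVs and fixed-effect covariances come
from the exact inverse of C (full blocks, no approximation), which is
affordable at the scale a breeding-program analysis reaches (a few
thousand genotypes).

Correctness is established against independent oracles rather than against
another mixed-model package: balanced one-way REML equals the ANOVA
method-of-moments estimators; MME solutions equal dense joint-covariance
GLS and conditional-expectation formulas; balanced BLUPs equal the
shrunken-group-mean closed form; the REML criterion is invariant to
fixed-effect coding.

## Relationship matrix

The additive relationship matrix uses the tabular method (a_ii = 1 +
0.5·a_sd, a_ij = 0.5·(a_js + a_jd)) over the topologically sorted pedigree;
unknown parents contribute 0 (unrelated, non-inbred founders — the standard
convention). Entries are exactly representable dyadic rationals, which the
tests exploit. An independent gene-dropping Monte-Carlo estimator (unique
founder alleles transmitted by fair coin flips; relationship = 2 × IBD
probability) serves as a stochastic cross-check. Note that with 10⁵ drops
each matrix entry carries a standard error of ~0.002, and across the
thousands of entries compared in the test suite an occasional |deviation| >
3 SE is expected Monte-Carlo behaviour, not disagreement.

## Cullis heritability

Per year × season, the stage-1 model is refit with genotype random and no
season term; H² = 1 − V̄_BLUP/(2σ²g) where V̄_BLUP is the mean variance of a
difference between two genotype BLUPs, computed exactly from the full PEV
block: V̄ = 2(q·tr(P) − 1'P1)/(q(q−1)). In the balanced IID case this
reduces to the entry-mean form σ²g/(σ²g + σ²ε/r), which the tests verify on
a grid. When σ²g is clamped at the boundary the heritability is reported as
0 with a flag.

## Outlier screening

Per trial, yields are screened by studentized residuals from a working
mixed model with genotype and the available design factors random
(intercept fixed). Conditional residuals are standardised by their exact
covariance R P R and mapped to externally-studentized (deletion) form;
two-sided t p-values are corrected by Holm's step-down within the trial
(the family is one trial, since models are fit per trial), default α =
0.05. Flagged yields are set to missing rather than deleting rows, so the
design structure survives.

A fixed-effects working model was rejected deliberately: with genotype
cell means, an unreplicated entry (augmented designs) has leverage one and
can never be tested, and a row-column model is parameterised heavily enough
that half of an 8σ shift disappears into the fit. The mixed working model
keeps every plot testable; measured operating characteristics under the
generator's conditions are sensitivity 1.0 for 8σ shifts and a family-wise
false-flag rate ≈ 0.02 at α = 0.05.

## Synthetic breeding program

The generator co-simulates pedigree and true breeding values so that
parental selection can act on the values themselves:

* founders N(0, σ²g); offspring = midparent + Mendelian deviate
  N(0, 0.5σ²g(1 − F̄_parents)), with F taken from the growing A-matrix
  diagonal;
* each crossing year, parents are truncation-selected (top
  `selection_fraction` by true value) — the genetic trend is therefore
  *realized*, and the ground truth is the OLS slope of true value on year
  of origin, not an imposed target;
* double/three-way/complex crosses are decomposed into chains of
  intermediate single crosses with their own pedigree entries one or two
  years earlier, keeping the pedigree strictly biparental for the tabular
  method;
* trials run over consecutive years × two seasons; each trial tests recent
  cohorts plus a fixed set of checks (connectivity between all year pairs),
  under one of four designs; per-trial error variances are drawn
  log-uniform over `sigma2_e_range`, creating the heterogeneity the
  inverse-SE² weights must absorb; DTF is genotype-constant with small
  trial jitter and a linear yield effect; missingness and recorded ±8σ
  outlier shifts are applied last.

Default conditions: 40 founders, 10 crossing years × 30 crosses, σg = 200
kg/ha around a 3 000 kg/ha baseline (stress-trial yields), error SD 245–500
kg/ha per trial, β_DTF = −15 kg/ha/day, 2 seasons, 100-entry trials, 4
checks, 5 % missingness, 1 % outliers. These put per-trial heritabilities
in the 0.2–0.9 band typical of stress breeding trials. Trial sizes are
configurable and not a claim about any particular program.

What the generator does *not* emulate: genomic markers, dominance and
epistasis, spatial autocorrelation beyond row/column effects, genotype ×
environment covariance structure, and — importantly — selection based on
*estimated* values. Real programs select parents on data that would also be
in the analysis; the generator's selection on true values is information no
estimator can access.

## Known limitation: shrinkage attenuation of trend estimates

Because parents are selected on their true values, part of each
generation's selection differential is invisible to the phenotype data, and
predicted breeding values shrink toward midparent expectations. The
regression of estimated breeding values on year of origin is consequently
attenuated by roughly (1 − mean reliability)-driven factors: at mean
reliability ≈ 0.6 the estimated slope runs ~20 % below the realized slope,
while at reliability ≈ 0.97 (near-noiseless trials) estimated and realized
slopes agree. The OLS slope SE does not cover this attenuation — it treats
breeding values as error-free observations. Users comparing programs should
read the estimated trend as a conservative lower bound at moderate
reliability; sign and ranking are robust (the no-pedigree BLUP mode
recovers the trend's sign reliably), absolute magnitude is not.

## Trend, panel, GGE details

* Percent-per-annum uses the mean of the regressed breeding values as
  denominator by default (`fitted_at_first_year` is available); the report
  names the rule used. OLS is unweighted by default; a reliability-weighted
  variant exists behind a flag.
* loess: tricube weights over the `ceil(span·n)` nearest points, local
  polynomial degree 2, span 0.75 by default; exact on polynomials of the
  fitted degree when span = 1.
* Elite panel thresholds are strict inequalities and deliberately have no
  hard-coded defaults — they are data-scale-dependent choices; ties at a
  `top_n` truncation break by reliability then genotype id, so selection is
  deterministic and order-invariant.
* GGE: environments centred, no scaling, row-metric preserving (genotype
  scores U·S, environment scores V); the ideal genotype sits on the
  average-environment axis at the largest genotype projection; stability is
  Euclidean distance to it in the PC1–PC2 plane. Incomplete tables are
  rejected rather than imputed.

## Degenerate inputs and tie-breaks

Zero-variance responses clamp σ²ε at the floor and flag it; constant
covariates are dropped with a warning; rank-deficient fixed blocks are
pruned by pivoted QR (earlier columns win); trials with < 2 residual df
skip outlier screening with a log entry; a constant genotype × environment
table raises a degenerate-table error; identical trend years raise an
undefined-slope error. All clamps and warnings surface in the pipeline
manifest so no numerical intervention is silent.

## Problem sizes in the test suite

The validation campaign sizes were chosen to exercise realistic structure
while keeping the suite quick on one CPU: unit fixtures use ~180-genotype
programs (6 crossing + 6 trial years); the trend-recovery experiment uses
20 seeded campaigns of 600 primary genotypes (10 + 10 years, ~3 500 plots
each); the acceptance script runs one such campaign per seed.
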