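# breedgain

Estimation of realized genetic gain in plant breeding programs from
unbalanced historical multi-environment trial data, using two-stage
weighted mixed-model analysis with a pedigree relationship matrix.

Breeding programs accumulate years of yield trials that were never designed
to be analysed together: genotypes turn over quickly, experimental designs
change (RCBD, augmented RCBD, alpha-lattice, row-column), error variances
differ wildly between trials, and only a handful of check varieties connect
the years. `breedgain` implements the analysis chain a quantitative
geneticist uses to extract the program's rate of genetic improvement from
such data, and ships a synthetic breeding-program generator with known
ground truth so every stage of the chain can be validated end to end.

## The model

**Stage 1** (per year): grain yield is modelled per trial year as

y = μ + g_i + β·DTF + s_j + (design blocking factors) + ε,

with genotype `g_i` fixed, days-to-flowering a fixed covariate, and season
and blocking factors (replicate/block or row/column, per design) IID
random. Adjusted genotype means (BLUEs), their standard errors, and weights
w = 1/SE² are extracted.

**Stage 2**: the BLUEs are combined across years in a weighted mixed model

BLUE_iy = μ + e_y + g_i + ε,  g ~ N(0, A·σ²g),  ε ~ N(0, R·σ²ε),

with year `e_y` fixed, genotype random with the additive (numerator)
relationship matrix **A** built from the pedigree by the tabular method,
and R = diag(1/w). The genotype predictions are estimated breeding values;
without a pedigree (A = I) they are ordinary BLUPs. Each prediction carries
a reliability r = 1 − PEV/σ²g from the inverse coefficient matrix of
Henderson's mixed-model equations.

Around this core:

* **QC** — trial filters (>20 % missing yield, absent design-mandated
  factor columns, implausible values) and per-trial outlier screening by
  the Bonferroni–Holm test on studentized residuals from a working mixed
  model; flagged yields become missing.
* **Heritability** — generalized (Cullis) H² = 1 − V̄_BLUP/(2σ²g) per
  year × season, with V̄_BLUP the mean variance of a difference between two
  genotype BLUPs, suited to severely unbalanced data.
* **Genetic trend** — OLS regression of breeding values on year of origin
  (the year the cross was made), year of testing, or year of release,
  reported in kg/ha/yr and %/yr, plus a tricube loess curve for
  short/long-term patterns.
* **Elite panel** — genotypes whose breeding value and reliability both
  exceed strict thresholds, plus a PCA biplot on A for diversity.
* **GGE stability** — environment-centred SVD of a genotype × environment
  mean table (no scaling, row metric preserving), ranking genotypes by
  distance to the ideal genotype on the average-environment axis.

All mixed models run on a self-contained REML engine (profiled likelihood
evaluated through the Cholesky factorisation of the mixed-model equations,
bounded quasi-Newton on log-variances) that is cross-checked in the test
suite against closed forms, ANOVA estimators, and dense GLS oracles.

## Worked example

```python
import breedgain as bg

cfg = bg.SimConfig(n_founders=20, crosses_per_year=20, n_years_crossing=8,
                   n_trial_years=8, entries_per_trial=60, seed=3)
ped, truth, pheno = bg.simulate_program(cfg)
cleaned, qc = bg.run_qc(pheno)
s1 = bg.stage1_by_year(cleaned)
a = bg.build_a_matrix(ped)
s2 = bg.stage2_blup(s1, a)
phen = s2.table[s2.table.phenotyped]
years = ped.set_index("genotype")["year_of_origin"]
trend = bg.trend_analysis(phen.set_index("genotype")["breeding_value"], years)
```

prints, step by step:

```
simulated 1632 plots, 180 genotypes, 85 cross intermediates
QC: 1517 records retained, 0 trials dropped, 15 outliers flagged
stage 1: 632 genotype-year BLUEs, H2 per season 0.43-0.88
stage 2: sigma2_g = 58236 (kg/ha)^2, mean reliability = 0.72
genetic trend: 110.5 +/- 5.6 kg/ha/yr (3.03 %/yr); simulator's realized slope 126.5
elite panel: 154 genotypes above thresholds
```

Reading: the simulated program improved its true breeding values by
126.5 kg/ha per year of origin (truncation selection of parents); the
pipeline recovers a trend of 110.5 kg/ha/yr from the noisy trials — the
gap is shrinkage of predicted breeding values at reliability ≈ 0.7, a
known attenuation of trend estimates from BLUPs (see
`docs/methods.md`). Per-season heritabilities (0.43–0.88) and the elite
panel come from the same two fits.

The same pipeline is scriptable from the shell:

```bash
breedgain simulate --config demo.yaml --out sim/
breedgain run --pheno sim/phenotypes.csv --pedigree sim/pedigree.csv --out results/
```

`run` writes every intermediate artifact (QC'd phenotypes, stage-1 BLUEs,
per-season H², stage-2 breeding values, trend JSON + loess points, panel)
and a manifest echoing the full configuration.

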