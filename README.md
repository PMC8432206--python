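# sgascreen

Competing-risks prediction of small-for-gestational-age (SGA) neonates from
maternal risk factors and second-trimester angiogenic biomarkers (sFlt-1 and
the sFlt-1/PlGF ratio), with screening evaluation at a fixed false-positive
rate.

## The model

SGA is treated as a spectrum condition living in two dimensions: gestational
age at delivery (GA) and the birth-weight Z score for gestational age
(Z_BW).  For each pregnancy:

1. **Prior.**  A maternal-factor prior — a bivariate Gaussian over
   (GA, Z_BW), factorized as a GA marginal times a Z_BW | GA conditional
   whose mean is linear in GA, with maternal covariates (smoking, previous
   SGA, parity, chronic hypertension, ...) shifting both means linearly.
   GA is truncated to [24, 43] weeks.

2. **Likelihood.**  Each biomarker, converted to multiples of the median
   (MoM) and log10-transformed, follows a Gaussian whose mean is a *folded
   plane* in (Z_BW, transformed GA): linear where the plane is positive,
   clamped at zero elsewhere, so unaffected pregnancies sit at MoM 1 while
   small preterm babies deviate.  For sFlt-1 the GA regressor is
   (GA − 33)⁻¹ with the mean forced to 0 at or after 32 weeks (the marker
   carries no birth-weight information at later gestations); for
   log10(sFlt-1 MoM / PlGF MoM) it is GA − 40 with no cut-off.  The
   reference coefficients are built in (`REFERENCE_SFLT1`,
   `REFERENCE_RATIO`), and `fit_folded_plane` re-estimates them from data by
   maximum likelihood or MCMC.

3. **Posterior risk.**  Bayes' theorem on a (GA, Z) grid: prior surface x
   likelihood surfaces, renormalized; the risk for any outcome definition
   (e.g. birth weight <10th percentile, Z < −1.2816, delivered before 32
   weeks) is the posterior mass of that orthant.

4. **Screening evaluation.**  Empirical detection rates at a fixed 10%
   false-positive rate, with paired method comparisons (discordant-pair Wald
   CI, exact McNemar test) on the same affected pregnancies.

Individual-level cohort data for the population this emulates are not
available, so a calibrated synthetic-cohort generator
(`sgascreen.cohort`) provides ground truth for every downstream stage.
See `docs/methods.md` for the model, calibration and limitations.

## Worked example

```sh
python analysis/01_simulate_cohort.py --out-dir results
python analysis/02_fit_likelihoods.py  --cohort results/cohort.csv --out-dir results
python analysis/03_compute_risks.py    --cohort results/cohort.csv --out-dir results
python analysis/04_screening_table.py  --risks results/risks.csv   --out-dir results
```

The first step prints the generator's calibration anchors:

```
cohort: n=40241 seed=42 -> results/cohort.csv
SGA<10th prevalence:          0.1003  (target ~0.10)
SGA<10th delivered <32w:      141  (~131 per 40241 expected at study scale)
PE prevalence:                0.0311  (target ~0.030)
PE among SGA<10th:            0.0734  (target ~0.074)
```

i.e. 10% of neonates are below the 10th birth-weight percentile by
construction, 141 pregnancies are both SGA<10th and delivered before 32
weeks, and pre-eclampsia occurs in 3.1% overall and 7.3% of SGA
pregnancies.  The second step refits the marker likelihoods; for the ratio
model the MCMC credibility intervals cover the generating coefficients:

```
ratio: MCMC posterior (mcmc, converged=True)
  intercept  est -0.317467  95% (-0.40538 to -0.23224)   generating -0.255556
    slope_z  est -0.158273  95% (-0.19524 to -0.12361)   generating -0.128029
   slope_ga  est -0.017566  95% (-0.02455 to -0.01087)   generating -0.016244
         sd  est  0.317123  95% ( 0.31483 to  0.31954)   generating  0.315649
```

The final step prints the detection table; for SGA<10th delivered <32 weeks
at 10% FPR (all strata):

```
    MF         detected  22/141 (15.6%)
    MF+sFlt-1  detected  28/141 (19.9%)
    MF+ratio   detected  35/141 (24.8%)
    MF vs MF+ratio         diff +13 (+9.2 pp; 95% CI 1.9 to 16.5; p=0.0241)
```

Detection by maternal factors alone is lower than in a real screening
population because the synthetic covariate effects are deliberately modest;
the marker methods add detection because the markers are generated from
their folded-plane models.  A `sgascreen` console command exposes the same
stages (`simulate`, `normalize`, `fit-likelihood`, `compute-risks`,
`screen`, `run`).

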