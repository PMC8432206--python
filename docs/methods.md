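# Methods

## The competing-risks formulation

The outcome of a pregnancy is represented as a point in the plane spanned by
gestational age at delivery (GA, decimal weeks) and the birth-weight Z score
for gestational age (Z_BW, dimensionless, chart-standardized so that the
10th percentile corresponds to Z = −1.2816 and the 3rd to Z = −1.8808).
"SGA below the pth percentile delivered before w weeks" is the lower-left
orthant {Z_BW < z_p, GA < w}.  A personalized joint density over this plane
is built in two stages — a maternal-factor prior updated by biomarker
likelihoods via Bayes' theorem — and a risk is the posterior orthant mass.
One model therefore serves every cut-off pair; nothing is refit when the
outcome definition changes.

## Prior

The prior is bivariate Gaussian, parameterized as a GA marginal times a
Z | GA conditional:

    GA       ~ Normal(mu_g(x), sigma_g),  truncated to [24, 43] weeks
    Z | GA=g ~ Normal(alpha(x) + beta * g, sigma_z)

where x are maternal covariates entering both means linearly.  The
conditional-mean factorization is equivalent to an unconstrained covariance
matrix and mirrors the mechanism: delivery gestation drives expected weight.
Truncation to [24, 43] (the livebirth registration range) is by
renormalization on the grid; it avoids assigning mass to impossible
gestations.  The slope beta > 0 encodes that earlier deliveries carry
smaller babies, which is what concentrates SGA mass at early gestations.

Published maternal-factor coefficient sets exist for this architecture but
are not reprinted here; the module accepts any coefficient file and ships
defaults calibrated to population anchors (below).

## Folded-plane marker likelihoods

For a marker observed at the 19+0 to 24+6-week visit, the log10 MoM value y
is modelled as

    y ~ Normal(m(z, g), sigma),   m(z, g) = fold(a + b*z + c*t(g))

with `fold(u) = max(u, 0)` for markers elevated in placental dysfunction
(sFlt-1, the sFlt-1/PlGF ratio) and `min(u, 0)` reserved for suppressed
markers (PlGF).  The fold is what reconciles a negative plane at healthy
(z = 0, term) coordinates with the MoM normalization contract that
unaffected pregnancies sit at log10 MoM = 0: deviation exists only on the
affected side of the plane.  The fold line is fixed at plane = 0, not
estimated.

Structural choices per marker (fixed inputs, not estimated):

| marker | t(g) | fold | applicability |
|---|---|---|---|
| sFlt-1 | (g − 33)⁻¹ | max-at-zero | mean forced to 0 for g ≥ 32 |
| sFlt-1/PlGF ratio | g − 40 | max-at-zero | all gestations |

The 32-week cut-off reflects the empirical finding that sFlt-1 carries no
birth-weight information at later gestations, and simultaneously guards the
reciprocal singularity at g = 33; the parameter validator enforces that a
reciprocal transform always comes with a cut-off below its centre.

Reference coefficients (used as generator truth and as demo defaults):
sFlt-1 (−0.028181411, −0.011182582, 0.001131449, sd 0.233381804); ratio
(−0.25555636, −0.12802946, −0.01624357, sd 0.31564903).

### Fitting

`fit_folded_plane` estimates (a, b, c, log sigma) with the structure fixed.

* **MLE** (default): Nelder–Mead on the exact folded log-likelihood from
  OLS-based and zero starts (the simplex method is robust to the fold kink),
  with equal-tailed Wald intervals from a finite-difference observed
  information matrix.  Directions with no curvature — e.g. the sFlt-1 slopes
  when no sampled pregnancy is fold-active — are reported as non-identified
  with unbounded intervals rather than spurious precision.
* **MCMC**: an affine-invariant ensemble sampler seeded at the MLE, with
  diffuse Normal(0, 10) priors on the plane coefficients and a half-Normal(10)
  prior on sigma (sampled on the log scale with the Jacobian term).
  Point estimates are posterior means; intervals are equal-tailed 95%
  credibility limits; convergence is diagnosed by cross-walker R-hat < 1.1
  and the acceptance fraction, and flagged on the result, never silent.

A known property of this likelihood, measured during development: the
intercept and Z slope sit on a strongly correlated ridge (only the ~3% of
pregnancies on the active side of the fold inform them), and the fold kink
breaks the second Bartlett identity, so Wald intervals *understate* the
ridge uncertainty while the ML point estimate has heavy-tailed sampling
spread along it (SD ≈ 0.011 for the Z slope at n = 200,000 under the
independent outcome prior).  MCMC credibility intervals track the actual
likelihood geometry and are the recommended uncertainty route; interval
coverage was verified by simulation (≥ 90% over replicate fits).  The
residual SD and, for the ratio model, the GA slope are well identified by
either route.

## Posterior risks on the grid

Densities are carried on a regular grid, by default [24, 43] weeks ×
[−6, 5] Z at step 0.05 (381 × 221 nodes) with trapezoidal weights.  The
posterior is formed in log space — log prior plus the Gaussian log-density
of each observed marker at every node — with one max-subtraction before
exponentiation, so products that would underflow double precision are
exact; an all-zero product raises an error rather than returning garbage.
Orthant masses use half-open cells with linear interpolation of the
integrand at each cut plane, which removes step artifacts when a cut-off
falls between nodes.  Verification: with the fold disabled the grid
posterior matches the conjugate closed-form Gaussian update to ≤ 1e-4 in
mean and SD, and halving the step perturbs reported risks by < 1e-3.

Markers are treated as conditionally independent given (Z_BW, GA):
likelihood surfaces multiply.  Correlated multi-marker likelihoods are out
of scope; the ratio and the single markers are alternative methods, never
combined with each other.

## MoM normalization

Raw concentrations are converted to MoM by a least-squares linear model of
log10(concentration) on configurable normalization covariates (GA at
measurement, maternal weight, analyzer indicator, ...), so that the median
MoM in unaffected pregnancies is 1 by construction and log10 MoM is the
likelihood's native scale.  The exact covariate set of the original
normalization is not public; the configurable regression reproduces the
contract without guessing unpublished coefficients.  Synthetic cohorts
bypass this module — their markers are generated on the MoM scale directly.

## Screening evaluation

The risk threshold is the smallest value such that the fraction of
unaffected pregnancies above it does not exceed the nominal FPR (ties
resolved conservatively, so the empirical FPR never exceeds nominal).  For
each outcome cut-off the unaffected pool is everyone not affected at that
cut-off — an SGA baby delivered after the GA cut counts as unaffected for
that row — and the same threshold serves all PE strata of the block.
Because two methods are evaluated on the same affected pregnancies, the
difference in detection is paired: the 95% CI uses the discordant-count
Wald method and the p-value is the exact McNemar binomial test on
discordant pairs.  (The original analysis does not name its paired test;
exact McNemar is this package's choice.)

## Synthetic cohort generator

The generator emulates a large routine-care screening population observed
at 19+0 to 24+6 weeks.  Covariates are sampled from reported population
marginals (normal approximations to median/IQR for continuous covariates,
reported prevalences for categorical ones); outcomes come from the prior;
PE labels from a logistic model in (−Z_BW, 40 − GA); markers from the
folded planes.  PE is a stratification label only and never feeds the risk
model.  One global seed spawns per-stage substreams (profiles, outcomes,
markers), so cohorts are bit-reproducible and adding a marker does not
perturb outcomes.

Default calibration, fixed once by simulation at n = 2,000,000 against
population anchors and then frozen:

* `sigma_g = 3.0`, `beta = 0.149` per week, `sigma_z = 0.9091` (unit
  marginal Z variance), `alpha = −5.6481`: give P(Z_BW < −1.2816) = 0.10,
  about 3.3 per 1000 pregnancies both SGA<10th and delivered before 32
  weeks (≈ 131 per 40,241), and unit-variance Z.
* Covariate shifts (Z: smoker −0.42, previous SGA −0.56, nulliparous −0.11,
  chronic hypertension −0.45; GA: chronic hypertension −1.5 weeks)
  reproduce the direction and rough magnitude of the reported SGA/non-SGA
  covariate contrasts (e.g. smokers ≈ 14% of SGA vs ≈ 7% of non-SGA).
* PE model (−4.3691, 0.2573, 0.3434): PE in ≈ 3.0% overall, ≈ 7.4% of
  SGA<10th, ≈ 33% of SGA<10th delivered < 32 weeks.

What the generator does **not** emulate: the inter-covariate correlation
structure of a real population; the excess of chart-defined SGA above the
nominal 10% seen with real weight charts; realistic preterm-delivery rates
at every gestation (a single truncated Gaussian GA marginal that carries
enough mass below 32 weeks necessarily carries too much mass between 32 and
37 weeks); marker–marker correlation beyond what (Z, GA) induces; twin
pregnancies, stillbirth timing or iatrogenic delivery.  Passing tests on
this cohort therefore demonstrate internal consistency of the machinery and
recoverability of the generating models — not clinical performance on real
data, where maternal-factor detection is substantially higher than the
synthetic covariate effects produce.

A separate *independent* outcome prior — GA ~ Normal(39.5, 2.0) truncated
to [24, 43], Z_BW ~ Normal(0, 1), no coupling — defines the
parameter-recovery protocols (`sgascreen.protocols`, `scripts/acceptance.py`).
Under it essentially no pregnancy delivers before 32 weeks, so the sFlt-1
plane coefficients are deliberately non-identified in those protocols and
only its residual SD is point-matched; the ratio model, whose fold is
active at all gestations, is fully recoverable.

## Problem sizes and numerical defaults

Parameter-recovery protocols use n = 200,000 (500,000 for the weakly
identified ratio intercept); interval-coverage replicates use the study
scale n = 40,241 with short ensemble chains (12 walkers, 800 steps, 300
burn-in); null-calibration replicates use 20 cohorts of 4,000 with a 0.1
grid step; the decile-calibration check runs the full 40,241-pregnancy
cohort.  Sizes were chosen so every check has adequate statistical
resolution at interactive runtimes.  Default tolerances: grid mass 1 ± 1e-6;
flat-likelihood identity 1e-10; conjugate oracle 1e-4; grid convergence
1e-3.

## Known limitations

* Wald intervals near the fold are anti-conservative (see Fitting); use
  MCMC intervals for inference on the plane coefficients.
* The single-Gaussian truncated GA marginal cannot match preterm rates at
  every gestation simultaneously; anchors prioritize the < 32-week rate.
* The MoM median model is a plain linear regression on log concentration;
  machine-specific calibration is out of scope.
* Risks are computed at the second-trimester visit only; time-updated
  third-trimester risks are not modelled.
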