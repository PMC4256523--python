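# Methods

This note documents the statistical models implemented in `jsyimpact`,
the defaults and their rationale, the synthetic-data generator used to
validate them, and the numerical choices that matter for reproducing
results.

## Problem

District-level maternal mortality ratios (MMR, maternal deaths per
100,000 live births) are rarely observed directly.  What exists is a
patchwork of sources — an administrative health bulletin reporting death
counts per district with incomplete coverage and systematic
under-counting, survey systems reporting at division or state level with
higher reliability, and program reports whose institutional-delivery
figures are over-stated.  The package estimates a complete district-year
MMR surface from this patchwork (stage 1) and then asks whether a
maternal cash-transfer program's intensity (JSY-supported delivery
proportion, or annual JSY expenditure) is associated with MMR change
(stage 2), propagating the stage-1 uncertainty through the stage-2
regression.

## Stage 1: spatio-temporal negative-binomial model

A death count `y` reported by source *s* for unit *u* (a district, a
division, or the state) in year *t* is modelled as negative binomial
with mean

    E[y] = exp(delta_s) * sum_{d in u} MMR_{d,t} * B_{d,t} / 1e5,

`B` being live births and `delta_s` a source effect capturing each
source's multiplicative reporting bias.  One designated reference source
(by default the state-level, gold-standard one) has `delta = 0` for
identifiability.  The latent surface is

    log MMR_{d,t} = mu + x_d' beta + a_{v(d)} + a_d
                  + (z + z_{v(d)} + z_d) (t - tbar) + xi_t

with districts nested in divisions nested in the state for both
intercepts and linear trends, standardized TFR and HDI as covariates,
and `xi` a smooth state-level non-linear trend with a second-order
random-walk prior, constrained orthogonal to the constant and linear
components so the trend decomposition is identified.  The dispersion
uses the mean–size parameterization `Var = m + m^2/k`.

Direct-MMR sources are converted to pseudo-counts via their reported
denominators (`deaths = round(mmr * live_births / 1e5)`); a direct-MMR
record without a denominator is rejected at validation rather than
modelled on the log scale.

### Inference

Joint MAP estimation over latent effects and log-variance
hyperparameters is ill-posed in hierarchical models (the posterior
density is unbounded along the `x -> 0, sigma -> 0` ridge), so the
package uses a nested Laplace scheme in the spirit of INLA:

1. Given hyperparameters (log dispersion and log random-effect sds), the
   latent field is maximized by damped Newton with analytic gradient and
   Hessian.  Under the log link the negative-binomial log likelihood is
   concave in the latent field, so this inner problem has a unique mode.
2. Hyperparameters are optimized on the Laplace-approximate marginal
   posterior (`L-BFGS-B`, bounded to keep the exponentials finite).
3. Posterior draws propagate hyperparameter uncertainty: hyperparameter
   vectors are drawn from a Gaussian at the marginal mode (curvature by
   central finite differences), and for each one the latent field is
   re-solved and drawn from its conditional Gaussian.

Predicted MMR excludes the source effects — it is the latent "true"
surface, not any source's reported level.  Intervals are the 2.5th and
97.5th percentiles of the exponentiated draws (numpy's default
linear-interpolation quantile).  An importance-weight effective sample
size against the exact joint density is reported in the diagnostics as
a check on the quality of the Gaussian approximation.

Default priors are weakly informative: `mu ~ N(5.7, 3^2)` (an MMR of
~300 with wide uncertainty), `beta ~ N(0, 1)` on standardized
covariates, state trend `z ~ N(0, 0.5^2)` per year, `delta ~ N(0, 1)`,
`log k ~ N(3, 2^2)`, and half-normal hyperpriors on the random-effect
sds (scale 0.3 for intercepts, 0.05 for slopes and the non-linear
trend).  All are overridable through `Stage1Spec.priors`.

### Accuracy

On the default synthetic scenario the 95% posterior intervals cover the
true district-year MMR in ≥ 90% of cases (checked over 20 replicates in
the test suite).  An ensemble-MCMC cross-check on a small instance shows
the Laplace posterior matches the exact joint posterior closely in the
center; on very small instances (4 observations) the Gaussian
approximation underestimates the extreme upper tail, which improves
quickly with data.  State-level trend estimates are unbiased across
replicates but individually noisy at 6 years of data — single-seed
declines scatter around the generative truth.

## Model selection: conditional predictive ordinates

`CPO_i = p(y_i | y_{-i})` is estimated two ways, both conditional on the
hyperparameters at their full-data modal values (the convention of
Laplace-approximation workflows — the hyperparameter posterior is common
to all leave-one-out sets):

- **importance_weighted** — the harmonic-mean identity
  `CPO_i = [E_post 1/p(y_i|theta)]^{-1}` on latent-field draws.  For
  observations whose mean depends on a single district-year cell the
  expectation is a one-dimensional Gaussian integral and is evaluated by
  deterministic quadrature; aggregated (division/state) observations use
  the draw-based estimator, whose weights can be heavy-tailed — an
  effective-sample-size guard (threshold 100) flags such observations
  and recomputes them by exact refit.
- **exact_refit** — the latent field is refitted without observation
  *i* and the held-out likelihood averaged over the refit draws.

On a 15-observation oracle instance the two agree within 10% per
observation (test suite).  Aggregated observations that are strong
outliers carry extra Monte-Carlo and approximation error in the
harmonic-mean estimator; the guard plus refit fallback bounds the
damage.  Model ranking uses the sum of log CPO over a configurable
ladder of specifications toggling covariates, the non-linear trend, and
source effects.

## Harmonization

- **Envelope benchmarking** (raking): district death counts are scaled
  proportionally so their sum matches a trusted higher-level envelope in
  each (unit, year); the float-rounding residual is absorbed so the
  conservation identity holds bit-exactly; an all-zero district group
  under a positive envelope falls back to an equal split with a warning.
  The pipeline relies on the stage-1 source effects to absorb reporting
  bias and does not rake by default; the operation is available for
  workflows that prefer pre-adjustment.
- **Delivery-proportion correction**: a per-district factor
  (survey proportion / bulletin proportion in one benchmark year) is
  applied to institutional and JSY delivery counts in every year —
  constant relative bias.  Factors above 1 are allowed with a warning.
  Corrected counts are floats so that applying a factor and its inverse
  round-trips exactly.

## Stage 2: draw-propagated multilevel regression

For each posterior MMR surface,

    log MMR_{d,t} = b0 + b1 Urban_d + b2 Lit_d + b3 ANC3_{d,t}
                  + b4 NJSY_{d,t} + b5 Exposure_{d,t}
                  + alpha_t + eta_d + phi_d Exposure_{d,t} + e_{d,t}

with year random intercepts, district random intercepts, and district
random exposure slopes (mutually independent components).  Percent
covariates stay on the 0–100 scale and delivery proportions on 0–1, so
`b5` is the log-MMR change per unit exposure proportion; expenditure
enters in lakh without rescaling, giving coefficients on the ~1e-6 to
1e-4 scale.

Each fit is REML over the log variance components with analytic
gradients and a bounded deterministic optimizer; the zero-variance limit
(no random terms) reduces exactly to OLS.  District slopes
`phi_d = b5 + BLUP_d` and their standard errors come from Henderson's
mixed-model equations, including the fixed-slope covariance term.

Across `n` draws, coefficients are pooled with Rubin-style rules: the
pooled estimate is the mean of per-draw estimates, the pooled variance
is the mean within-draw variance plus `(1 + 1/n)` times the between-draw
variance, with intervals and p-values from the normal reference.  The
empirical 2.5/97.5 percentiles of the per-draw estimates are emitted
alongside for comparison.  A run aborts if more than 5% of per-draw
fits fail.  A district slope is called significant when its pooled 95%
interval excludes zero.

### Calibration

Validated on scenarios where the regression is correctly specified (no
covariate effects on mortality, no district-specific mortality trends,
exposure measured without error): the null exposure effect is rejected
in ≤ 10% of replicates at nominal 5% (empirically the procedure is
conservative), power at a true effect of −0.6 with low stage-1 noise
exceeds 80%, detection is monotone over effect sizes
{0, −0.15, −0.3, −0.6}, and widening the stage-1 posterior widens the
pooled interval.

A deliberate property of the *full* pipeline, as opposed to the
estimator: when the bulletin's institutional proportions saturate near 1
(which happens when true uptake is high and the reporting factor is
small), the constant-relative-bias correction can no longer recover the
true exposure, and the resulting exposure measurement error attenuates
the exposure coefficient substantially.  This mirrors the acknowledged
fragility of one-year benchmark corrections in the real setting and is
one reason full-chain exposure estimates are biased toward zero.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the
study conditions:

- 12 districts in 3 divisions, years 2005–2010, ~1.2 M people per
  district (±25%), crude birth rate 25/1,000, stillbirth rate 15/1,000
  (per 1,000 total births, deliveries ≈ total births).
- Baseline log MMR `log(371)`; district intercept sd 0.18 and division
  sd 0.10 on the log scale; covariate effects +0.15 per TFR child and
  −1.2 per HDI unit around fixed centres (3.5, 0.5).
- Secular trend −0.007/year (mean) with district sd 0.012, plus a
  state-level RW2 perturbation (scale 0.008) orthogonalized to the
  linear trend; program effect −0.223 per unit JSY delivery proportion.
  Together these produce a state MMR decline of roughly 12% over the
  period with wide inter-district variation.
- Institutional delivery rises 23.9% → 55.9% and the JSY share of
  institutional deliveries 14% → 80% at state level; districts shift
  both the level (logit sd 0.15) and the growth rate (logit sd
  0.15/year) of the uptake curves, producing institutional-delivery
  increases spanning roughly 10–55 percentage points across districts.
  The growth spread is what makes the exposure identifiable against
  district and year effects.
- Three sources: a district bulletin (bias 0.85, coverage 0.9), a
  division-level system (unbiased, complete), and a state-level
  gold standard (unbiased, complete, the reference).  Counts are
  negative binomial with size 25.  Bulletin institutional-delivery
  proportions are inflated by `1/factor` with true factors uniform on
  (0.34, 0.97), capped at a reported proportion of 0.98; the survey
  benchmark reports the truth in 2007.  Expenditure is 0.03 lakh per
  reported JSY delivery with 5% log-normal noise.
- One master seed spawns independent substreams for truth,
  observations, and the program panel, so adding a source never
  perturbs the generated truth.

What the generator does *not* emulate: real district geography or
spatial adjacency, fiscal-year reporting, migration, year-varying
source bias, heaping/digit preference in counts, and correlation
between uptake and mortality shocks.  Passing tests demonstrate
statistical correctness of the estimators under the stated generative
assumptions, not agreement with any real administrative series.

## Numerical choices and degenerate inputs

- All fits are deterministic given seeds; stage-1 draws derive from
  `Stage1Spec.seed`, stage-2 pooling from `Stage2Spec.seed`, and the
  pipeline derives stage seeds from its single `--seed`.
- Inner Newton: tolerance 1e-8 on the gradient max-norm, backtracking
  line search, ridge fallback if the precision matrix loses positive
  definiteness; linear predictors above 40 are treated as line-search
  overflow and rejected.
- Hyperparameter curvature: central differences with step 1e-3;
  eigenvalues clipped at 1e-6 (clipping count reported in diagnostics).
- REML variance components are bounded in log space
  (`var_lower = 1e-10` times the outcome variance); components at the
  lower bound are reported as boundary fits.
- Raking of an all-zero group under a positive envelope: equal split
  (deterministic); NaN envelope cells leave districts untouched.
- A single-source dataset silently disables source effects (warning
  logged); constant exposure columns raise a collinearity error naming
  the term.
- Rounding conventions: headline percent changes to the nearest
  integer, district tables to one decimal, coefficient tables to three
  decimals with scientific notation for interval bounds that would
  round to 0.000 and p-values below 0.0005 printed as "0".

## Problem sizes used in the test suite

Chosen to keep the full suite a few minutes on one CPU while leaving
each check statistically meaningful: stage-1 coverage over 20
replicates at 300 draws; stage-2 type-I error and power over 100
replicates each at 50 draws per replicate; propagation monotonicity
over 20 replicates; CPO oracle equivalence on a 15-observation
instance with 20,000 (importance) / 50,000 (refit) draws; production
defaults are 1,000 draws in both stages.

## Known limitations

- The Laplace posterior can under-cover in extreme tails for very small
  datasets; the MCMC cross-check quantifies this on a toy instance.
- CPO for aggregated observations relies on draw-based estimation with
  an ESS guard rather than exact quadrature.
- The stage-2 model, like the analysis it implements, is associational:
  exposure is not randomized, and the year intercepts absorb any
  state-wide component of the program effect, so `b5` is identified
  from differential uptake across districts.
- Fiscal-year sources must be mapped to calendar years upstream.
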