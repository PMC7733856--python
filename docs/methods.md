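# Methods

This note documents the models implemented in `infoseek`, the assumptions
behind the synthetic-data generator, and the numerical choices made where
the design was genuinely open.

## The task being modelled

A two-alternative perceptual judgment with costed information seeking. On
each trial the observer judges which of two flickering-dot boxes contains
more dots (one box always holds a 313-dot baseline; the other holds more),
reports signed confidence on a six-point scale ("sure left" = 1 … "sure
right" = 6, collapsing to three magnitude levels per side), and may then pay
5 or 20 points (fixed per 25-trial block, four blocks) to view a stronger
version of the stimulus before a final decision. Only the final decision is
incentivized: 100 points if correct, 0 otherwise, so per-trial points are
`100·final_correct − cost·sought` by construction. Task difficulty is
calibrated per observer in a 120-trial staircase phase targeting ~71%
accuracy.

## Perceptual model

Internal evidence on a trial is a single Gaussian draw
`x ~ N(side · d′/√2, 1)` with `d′ = sensitivity · log(1 + Δdots/313)` and
`side = ±1`. Accuracy is therefore `Φ(d′/√2)`, a Weber-like psychometric
function on the 313-dot baseline; the √2 is the usual 2AFC
difference-of-two-channels convention. A lapse rate in [0, 0.05] mixes in
random responses. Confidence is |x| cut at two increasing criteria into
levels {1, 2, 3}. If the observer seeks, a second draw at `post_multiplier`
(default 3) times the calibrated log-strength is added to x before the
final choice; the combined evidence then also sets final confidence. Without
seeking, the final decision deterministically repeats the initial one — the
simulator does not model unprompted changes of mind. At the default
multiplier the stand-alone accuracy of the stronger stimulus is ~95%, so
seeking reliably improves final accuracy.

## Staircase calibration

Two-down-one-up on log dot difference: two consecutive correct responses
make the task harder by one step, each error makes it easier; the step
(0.2 log-units initially) is halved after the first 3 reversals, and the
returned dot difference is the exponentiated mean of the last 6 reversal
points, rounded to an integer ≥ 1. The asymptotic convergence point of this
rule is √(1/2) ≈ 70.7% correct, matching the ~71% target. An observer whose
accuracy stays below 60% even at the maximum difference (313 dots) raises a
calibration failure.

A single 120-trial run carries an irreducible accuracy spread of roughly
4–6 percentage points — an information limit of 120 Bernoulli trials, and
similar in size to the between-subject spread such calibration phases show
in practice. The tests and the acceptance script therefore measure the
procedure's convergence point by averaging over ~20 independent replicate
calibration-plus-probe runs rather than trusting any single run.

## Seek policy and predictor encoding

The seek decision is Bernoulli with
`P(seek) = logistic(β0 + β1·Confidence + β2·Cost)`. Confidence enters as a
z-scored version of the 3-level rating; cost as a high-cost indicator
(1 = 20 points). Inside the generator the encoding uses the closed-form
z-score of a uniform 3-level variable, `(level − 2)·√(3/2)`; the fitting
pipeline re-standardizes empirically across all pooled trials. When the
empirical confidence distribution is asymmetric the two encodings differ by
an affine map, which the fitted intercept and slope absorb — recovered
parameters are reported on the empirical-encoding scale.

Subjects seeking on fewer than 5% or more than 95% of trials (bounds
inclusive) are excluded before hierarchical fitting; near-degenerate seek
behaviour carries almost no information about the policy slopes.

## Population model and generator defaults

Each subject's coefficient k is drawn from
`β_{k,i} ~ N(µ_Bk + ρ_k · Dogmatism_i, σ_Bk)` with dogmatism standardized.
Defaults: `µ_B = (−0.5, −1.0, −0.8)`, `σ_B = (1.0, 0.5, 0.5)`,
`ρ = (−0.24, +0.15, 0)` — negative confidence and cost slopes, a
dogmatism-linked reduction in baseline seeking, a dogmatism-linked weakening
of the confidence–seeking coupling, and no dogmatism effect on cost
sensitivity. These values put almost all subjects inside the 5–95%
inclusion band and give an overall seek rate near 35%.

Factor scores are generated with the qualitative structure the analyses
assume: dogmatism is a positive linear + quadratic function of political
orientation; belief superiority is negative-linear and positive-quadratic in
orientation plus positively related to dogmatism; all three columns are
standardized after generation. Demographic covariates (age, gender,
education) are generated independently of the factors; real questionnaire
data would show correlations the generator does not emulate, so passing
tests demonstrate correctness of the estimation machinery, not robustness
to confounded covariates. Other simplifications relative to real data: no
learning or fatigue across blocks, no reaction times, no choice reversals
without seeking, and confidence criteria that are fixed within subject.

## Hierarchical estimation

The joint posterior over `{µ_B, σ_B, ρ, β_i}` under the Bernoulli-logistic
likelihood uses weakly informative hyperpriors: `Normal(0, 5)` on each µ_Bk
and ρ_k, `Half-Normal(2.5)` on each σ_Bk — diffuse on the logit scale.

Sampling is Metropolis-within-Gibbs, vectorized across subjects:

* **Subject coefficients** — component-wise Gaussian random-walk Metropolis
  with per-subject step sizes adapted during warmup toward a 0.44
  acceptance rate; all subjects are proposed and accepted in parallel since
  they are conditionally independent given the group level. Three sweeps
  per scan cut the autocorrelation between levels.
* **(µ_k, ρ_k)** — exact conjugate bivariate-normal draw: given the subject
  coefficients this block is a Bayesian linear regression of β_k on
  dogmatism.
* **σ_k** — random-walk Metropolis on log σ with warmup adaptation.

Defaults: 4 chains, 1000 warmup + 1000 kept draws, overdispersed chain
starts jittered around each subject's empirical seek-rate logit.
Convergence is summarized by rank-normalized split R-hat and bulk effective
sample size (via arviz) for every parameter; exceeding the threshold
(default 1.01, deliberately strict) logs a non-fatal warning. The
population-scale parameters σ_B mix slowest; at default settings their
effective sample sizes are in the hundreds.

An embedding slope ρ_k is reported as significant when its central
(equal-tailed) 95% credible interval excludes zero; intervals are closed,
so an endpoint exactly at zero does not exclude it.

Shrinkage note: because the three coefficients are correlated through the
design (the cost indicator has mean ≈ 0.5), posterior means shrink toward
the covariate-shifted population centre as whole vectors; coordinate-wise
shrinkage of β0 alone can be violated for individual subjects even when
vector shrinkage holds for essentially all of them. Tests check the vector
form.

## Subject-level analyses

* **Standardized regressions.** Continuous variables z-scored, gender
  dummy-coded (female reference, two indicators to accommodate a third
  category), education treated as a z-scored ordinal, objective stimulus
  strength as log dot difference. ΔR² compares the full model with the same
  model excluding the focal predictor (always ≥ 0 for nested OLS).
  One-tailed tests are a reporting option taking the hypothesized direction
  as an argument. Rank-deficient designs raise an error naming the
  offending columns.
* **Polynomial factor fits.** Linear (`1, x`), quadratic (`1, x²`) and
  combined (`1, x, x²`) candidates compared by BIC; ties within numerical
  noise resolve toward fewer parameters.
* **Pooling.** Sample pooling concatenates subject tables, labels studies
  and re-standardizes continuous columns on the pooled sample, so pooled
  coefficients are standardized on the combined population.
* **Mediation.** Mediator and outcome models are linear OLS on standardized
  subject-level aggregates (final accuracy as a linear proportion);
  coefficient draws come from the multivariate-normal approximation to the
  OLS sampling distributions, with percentile intervals over 1000+ draws.
  The per-draw identity `total = ACME + ADE` is exact for linear models.
  The proportion mediated uses the per-draw ratio with a median point
  estimate.

## Problem sizes and reproducibility

Every stochastic routine takes an explicit integer seed; regenerating with
the same seed reproduces tables byte-for-byte, and a full pipeline run is
checksum-identical when repeated. The test suite exercises recovery at the
full 568-subject, 100-trial scale (with a 200-subject variant at lighter
sampler settings), null calibration over 20 replicate zero-effect fits at
200 subjects, and mediation interval coverage over 100 replicates at
n = 500. The acceptance script regenerates its quantities from scratch at
24 staircase replicates × 1000 probe trials and one 50-subject cohort.

## Known limitations

* The sampler is a random-walk scheme, not gradient-based; it is tuned for
  this model's scale (hundreds of subjects, ~100 trials each) and would mix
  poorly with far fewer trials per subject.
* The confidence model is a fixed-criterion signal-detection read-out; no
  metacognitive noise or alternative confidence-formation architectures.
* Mediation assumes linear models and sequential ignorability; no
  sensitivity analysis is provided.
* The generator's covariates are independent of the factors by design, so
  covariate-adjustment code paths are exercised but not stress-tested
  against realistic confounding.
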