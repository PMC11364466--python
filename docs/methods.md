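# Methods

## The scientific problem

In delayed-estimation spatial working memory, a participant sees a target at
some angle on the screen, holds it over a delay, and reproduces its location
with a joystick. Response errors are not pure noise: responses drift toward
the diagonal of the screen quadrant the target appeared in, and the drift
grows with the target's distance from the diagonal. The category-adjustment
account explains this as an optimal combination of two representations — a
fine-grained memory of the true angle and a categorical prototype (the
quadrant diagonal) — weighted by their relative precisions. This package
decomposes each participant's responses into the two underlying quantities
(memory inexactness and prototype bias), relates them to parcellated brain
activity, and characterizes how stably such brain-behavior associations can
be detected as a function of sample size.

## The category-adjustment model

The response angle R on a trial with target angle mu (degrees,
counter-clockwise from the positive x-axis) and quadrant prototype rho
(45/135/225/315 deg) is modeled as

    R ~ StudentT(nu,  lambda_j * mu + (1 - lambda_j) * rho,  sqrt(lambda_j) * sigma_M_j)

    lambda_j = sigma_P_j^2 / (sigma_P_j^2 + sigma_M_j^2)

for participant j, where sigma_M is the SD of the fine-grained memory (memory
inexactness, degrees), sigma_P the SD of the prototype representation, and
lambda the confidence in the fine-grained memory. Prototype bias is 1 -
lambda. In error coordinates (y = R - mu, d = rho - mu, both wrapped to
(-180, 180]) the mean is (1 - lambda) d, so an ordinary regression of error
on prototype offset estimates 1 - lambda; this is the method-of-moments
oracle used throughout the tests.

**Choice of the observation scale.** The precision-weighted combination of
two Gaussian cues with SDs sigma_M and sigma_P has posterior SD
sqrt(lambda) * sigma_M. The same expression is the SD of the composed
response lambda*M + (1-lambda)*P, because under the lambda identity

    lambda^2 sigma_M^2 + (1 - lambda)^2 sigma_P^2
      = lambda sigma_M^2 (lambda + (1 - lambda)) = lambda sigma_M^2

(using (1-lambda) sigma_P^2 = lambda sigma_M^2). The two natural readings of
the model's noise therefore coincide, and sqrt(lambda) * sigma_M is the
likelihood scale. The identity is asserted to 1e-10 in the tests, both on the
deterministic formula and draw-wise on posteriors.

**Hierarchy and parameterization.** Fits are run separately per study.
Per-participant (log sigma_M_j, log sigma_P_j) are varying effects around
study-level means with half-normal(1) scales, written non-centered
(participant value = group mean + group scale x standard-normal deviate);
lambda_j is a deterministic transform, which enforces positivity and the
lambda identity by construction. One degrees-of-freedom parameter nu is
shared within a study, with a Gamma(2, 0.1) prior on nu - 1 (the shift
guarantees a finite mean and keeps nu > 1). A single-participant fit drops
the (unidentifiable) group scales and places the priors directly on the
participant's log sigmas.

**Priors and the preliminary fit.** Group-mean priors are Normal with SD 2 on
the log scale, centered — when the preliminary fit is enabled (default) — at
the optimum of a pooled one-level Student-t fit of the same study. The
centers only position the prior in a sensible region; a prior-width check
compares prior SD to posterior SD for every reported parameter and warns when
the prior is not at least 10x wider.

**Measures.** Memory inexactness is the posterior mean of sigma_M (degrees);
prototype bias is 1 minus the posterior mean of lambda. One pair per
participant.

## Posterior computation

Posteriors are explicit log-density functions sampled with affine-invariant
ensembles (emcee), using a differential-evolution move mixture (80% DEMove,
20% DESnookerMove), which mixes markedly better than the default stretch move
on these correlated targets. Each fit runs two independently seeded
ensembles. Diagnostics operate at two levels: bulk/tail ESS treats every
walker as a chain, so within-walker autocorrelation is fully visible; R-hat
is computed across the independently seeded ensembles, with each ensemble
collapsed to one chain by rotating through its walkers (draw t comes from
walker t mod W at step t). Walker-as-chain split R-hat is dominated by the
sqrt(1 + tau/n) inflation of finite autocorrelated chains — which ESS already
quantifies — whereas ensemble-level R-hat measures what the statistic is for:
disagreement between independent runs. The convergence gate flags any
parameter with bulk or tail ESS below 400 or R-hat outside [0.99, 1.01];
divergence/tree-depth notions of Hamiltonian samplers do not apply to
ensemble moves, so the acceptance fraction is recorded instead. At default
settings the hierarchical group-scale parameters (tau) can retain R-hat
around 1.01-1.02 on cohort-sized studies — the funnel mixes slowly — and the
report flags exactly those; per-participant posteriors and the derived
measures pass. Prior- and posterior-predictive
checks simulate replicate datasets and compare the error SD and
bias-toward-prototype of replicates with the observed data.

Default sampler sizes (warmup/draws/thin): 1200/1200/4 for the
category-adjustment model, 3000/5000/10 for the brain-behavior model (cheap,
low-dimensional), reduced to roughly 250/300/2 for the bootstrap's inner fits.
These defaults were chosen so the convergence gate passes with margin on
cohorts of the bundled sizes.

## Behavioral preprocessing

Pixel offsets from screen center convert to degrees of visual angle per axis
as atan(offset_cm / viewing_distance_cm); Cartesian responses then convert to
polar (angle, amplitude) about the screen center. Errors decompose into a
signed angular error (wrapped to (-180, 180], positive counter-clockwise) and
an amplitude ratio. A trial is excluded when |angular error| > 45 deg, the
amplitude ratio leaves [0.5, 1.75] (closed interval: boundary values are
kept), or the response falls outside the target's quadrant. All three rules
are evaluated for every trial and all violations recorded, so quadrant-only
misclassifications are separable from gross angular errors; neither rule
subsumes the other (a response can change quadrant with a small error near a
boundary, or err by 50 deg inside its own quadrant). Only angular errors are
modeled downstream; amplitude errors are used by the filters alone.

## GLM stage

The activation stage is a desk-scale stand-in for a full fMRI pipeline: it
consumes parcellated time-series (frames x regions) rather than images.
Design matrices contain per-phase boxcars (encoding, delay, response, and
optionally an attention cue) convolved with a double-gamma HRF (response
delay 6 s, undershoot delay 16 s, dispersions 1, undershoot ratio 1/6, peak
normalized to 1 — canonical defaults, configurable); trials flagged as
behavioral outliers are removed from the phase regressors and given their own
unassumed FIR columns (one per TR bin from trial onset to offset + 16 s); six
motion parameters expand to 18 nuisance columns (parameters, first
derivatives, squares); an intercept and linear drift close the matrix, and a
rank check names collinear columns rather than letting least squares silently
pick a solution. Betas are ordinary least squares per region, averaged
unweighted into networks. Outlier participants are screened per phase by
correlating each participant's region-wise beta vector with the group mean
(including the candidate by default; leave-one-out by flag) and flagging any
participant whose correlation deviates from the phase mean by more than 3 SD;
identical maps (zero spread) exclude nobody, and zero-variance vectors go to
a review list instead of being dropped.

## Brain-behavior association

Activity, memory inexactness and prototype bias are standardized to mean 0,
SD 1 across all participants (population-SD convention), so coefficients are
fully standardized. One Student-t regression per (network, phase):

    activity ~ StudentT(nu, alpha_study + b1 * z_inexactness + b2 * z_bias, sigma)

with non-centered study intercepts (collapsing to a single-level intercept,
with a warning, when only one study is present), Normal(0, 10) priors on
coefficients, half-Cauchy(2.5) on scales, Gamma(2, 0.1) on nu - 1. Both
predictors enter jointly; their collinearity (r ~ 0.66 in the default cohort)
is reported alongside the coefficients, and no multiplicity correction is
applied — the headline outputs are posterior sign probabilities P(b > 0) and
P(b < 0), with thresholds left to the reader.

## Bootstrap power

At each target sample size, participants are resampled with replacement
(unstratified by study; duplicates are independent rows) and the association
model refitted with reduced sampler settings. Power at a size is the
proportion of resamples in which at least 95% of the coefficient's posterior
lies on one side of zero, i.e. max(P(b>0), P(b<0)) >= 0.95. The
across-resample 2.5/97.5 percentiles of posterior-mean estimates form the
stability interval; the stability threshold is the smallest size from which
zero stays outside that interval for all larger sizes ("not reached" when it
never does). Inner-fit failures are counted, and a failure rate above 5%
invalidates that size's power estimate. A resample containing a single study
degrades to the single-level model rather than crashing.

Note that under a null effect this "power" statistic is not 5%: the exclusion
event is two-directional (~10% asymptotically) and the bootstrap conditions
on the realized cohort, so across null cohorts the statistic has mean ~0.16
with a long right tail (an OLS-approximation simulation of the null
distribution is the oracle for the tests). The full published-style grid
(sizes 15-155, 1000 resamples) is configurable; bundled analyses run reduced
grids (e.g. 5 sizes x 60 resamples) to keep a laptop-scale runtime.

## The synthetic cohort generator

The generator emulates: six studies with 20-36 possible target angles each
(never on the cardinal axes), constant per-study target amplitude, 60 trials
per participant (within the 20-80 range of the emulated designs), 155
participants total; per-participant (log sigma_M, logit lambda) bivariate
Gaussian with the Gaussian correlation calibrated (deterministic bisection)
so that sigma_M and 1 - lambda correlate at latent_corr = 0.66 across
participants; responses drawn directly from the marginal
StudentT(nu, lambda*mu + (1-lambda)*rho, sqrt(lambda)*sigma_M) — the same
first two moments as sampling M and P separately, and exactly the fitted
likelihood, which makes parameter recovery well-posed; sigma_P derived from
(sigma_M, lambda) so the lambda identity holds to machine precision; outlier
trials injected at 2% with uniform angle within +-180 deg of the target and
uniform amplitude in [0.3, 2] x target amplitude, so some violate each filter
rule; response amplitudes otherwise log-normal around the target amplitude
(SD 0.06); one shared nu = 8 per study. Population defaults (sigma_M
log-normal with median 5 deg, spread 0.35; logit lambda mean 1.9, SD 0.8)
were picked as plausible for spatial recall at these eccentricities; they are
free parameters of the generator, not calibrated to any dataset. Activity is
linear in the standardized true measures with Student-t(30) residuals and
study intercepts (SD 0.3); BOLD time-series are design-matrix signal plus
optional AR(1) noise.

What the generator does *not* emulate: eye movements, attention-cue button
presses, realistic fMRI spatial/temporal structure, per-quadrant prototype
idiosyncrasies, boundary repulsion, or reaction times. Passing recovery tests
on these cohorts therefore shows the estimators are correct under the model's
own assumptions, not that the model is right for any real dataset.

**A calibration caveat worth knowing.** When truth is drawn from the
generator's default *correlated* population, the fitted model (independent
varying effects for log sigma_M and log sigma_P, shared nu) is mildly
misspecified: nu is then overestimated and per-participant 90% credible
intervals for sigma_M cover truth at roughly 75% rather than 90%. With truth
drawn from the model-matched population (independent log-normals, via
`CohortConfig.sigma_p_pop`), coverage is nominal and nu is recovered. Point
estimates and rank orderings are accurate in both regimes (r > 0.9 against
truth); the recovery tests use the model-matched population, and the caveat
applies verbatim to real data, whose population structure is unknown.

## Numerical choices and degenerate inputs

- Angles are stored in [0, 360); signed differences wrap to (-180, 180], with
  the boundary mapped to +180. Cardinal-axis target angles raise an error
  (their quadrant is undefined); responses on a cardinal axis simply fail the
  quadrant match.
- The sampler rejects proposals with any coordinate beyond |40| on the
  unconstrained scale (overflow guard far outside any plausible posterior).
- Standardization requires >= 2 distinct values; Pearson correlation requires
  >= 3 pairs and nonzero variance; both raise errors otherwise.
- Participants with < 3 kept trials, or with all kept trials at one target
  angle (lambda weakly identified), are flagged with warnings but kept.
- Injected-outlier trials are excluded before model fitting (and are flagged
  in the generator's ground truth); the exclusion is configurable upstream.
- The global pipeline seed fans out as seed + fixed per-stage offsets, so any
  stage reruns reproducibly in isolation; bootstrap index plans are drawn once
  per (seed, size grid) and are byte-reproducible.

## Known limitations

- Ensemble MCMC walkers are interacting, so walker-as-chain ESS/R-hat are
  approximations; two independent ensembles per fit restore sensitivity to
  genuine non-convergence, and diagnostics gates are enforced, but extremely
  multimodal posteriors would be better served by HMC.
- Shared-nu hierarchical Student-t fits overestimate nu when per-participant
  scale heterogeneity deviates from the assumed population (see the
  calibration caveat above).
- The GLM stage assumes the canonical HRF for all participants and models
  drift as a single linear term; no autocorrelation correction (betas remain
  unbiased under AR(1) noise, their standard errors are not used downstream).
- The power analysis treats the inner sampler's reduced settings as adequate
  for posterior sign-mass decisions; the failure-rate guard catches gross
  breakdowns but not subtle under-sampling of tails.
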