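# Methods

This note documents the models, estimators and numerical choices behind
`flashbeep`, in the order the pipeline runs.

## The observer model

The generative model has five parameters: the causal prior `p_common` in
[0, 1]; the numeric prior mean `mu_P` and SD `sigma_P` (stimulus-count
units); and the auditory and visual measurement noise SDs `sigma_A`,
`sigma_V` (all SDs strictly positive).  The marginal likelihoods of the two
causal structures are Gaussian integrals with closed forms:

    p(x_A, x_V | C=1) = N(x_A - x_V; 0, .) x N(.; mu_P, .)   (one latent count)
    p(x_A, x_V | C=2) = N(x_A; mu_P, sqrt(sigma_A^2 + sigma_P^2))
                        x N(x_V; mu_P, sqrt(sigma_V^2 + sigma_P^2))

implemented on the log scale through the likelihood ratio, so the posterior
`p(C=1 | x_A, x_V)` is exact and stable for extreme samples.  A dense
1-D/2-D quadrature oracle (in the test suite) verifies the closed forms to
1e-6.  Conditional estimates are the precision-weighted means; the final
estimate follows one of three decision strategies.  Model selection resolves
the tie `p(C=1|.) = 0.5` in favour of segregation (the strict-inequality
reading of the selection rule); probability matching consumes one uniform
draw per trial.  Continuous estimates map to buttons by rounding half-up and
clamping to {1..4}; out-of-range estimates take the closest button.  The
clamping convention is our choice -- the mapping is only stated as "closest
button" for in-range values -- and is deterministic with measure-zero ties.

## Simulated maximum likelihood

Predicted response distributions per condition come from Monte-Carlo
marginalisation: 5000 internal samples per condition during fitting, 1e5 for
final reported predictions.  One fixed array of standard-normal (and
uniform, for probability matching) draws per fit provides common random
numbers across parameter proposals, making the objective deterministic and
smooth enough for direct optimisation.  Probabilities are floored at
1/(10 * n_samples): a Monte-Carlo zero is not a true zero, and a single rare
response must not contribute -infinity.

Optimisation is Nelder-Mead on transformed coordinates (logit `p_common`,
log SDs), seeded by a coarse lattice search over
p_common in {0.1, 0.5, 0.9} x mu_P in {1.5, 2.5, 3.5} x sigma_P in {1, 3}
x sigma_A, sigma_V in {0.3, 1, 2}; the ten best lattice points start
simplices (maxiter 300, xatol 2e-3, fatol 0.01).  Two details matter in
practice and are deliberate:

- an explicit initial simplex with steps (0.75, 0.3, 0.3, 0.15, 0.15) on the
  transformed scales -- scipy's default perturbs a coordinate sitting at 0
  (e.g. logit(0.5)) by 2.5e-4, which freezes `p_common` entirely;
- a polish stage: a dense coordinate sweep over `p_common` at the incumbent
  solution (cheap, because for fixed SDs the per-sample estimates and
  likelihood ratios are reusable) followed by one simplex restart.  The
  likelihood surface has a ridge trading `p_common` against the numeric
  prior, and the restart reliably escapes premature collapse on it.

Goodness of fit is Nagelkerke's R^2 against uniform guessing (p = 0.25 per
button); model evidence is the BIC approximation LL - 0.5 m ln(n).  Group
comparison is random-effects Bayesian model selection: a variational
Dirichlet scheme (alpha_0 = 1) estimates population model frequencies,
exceedance probabilities come from 1e5 Dirichlet samples, and the Bayes
omnibus risk (free energy of the random-effects model against the
equal-frequency null) protects them: pEP = EP (1 - BOR) + BOR/K.

Single-parameter refits (`p_common` or `sigma_V`, all else fixed) evaluate
the likelihood on a dense transformed grid (41 logit- or log-spaced
candidates, precomputed once per reference fit) with parabolic refinement
around the grid minimum.  This makes each refit ~0.03 ms, which the decile
and history analyses (thousands of refits per participant) require; the grid
covers (0, 1) for `p_common` and a factor 4 around the reference for
`sigma_V`.  Subsets under 32 trials refit with a warning.

## The audiovisual weight index and circular inference

Within each cell of the 2 (disparity: small <= 1 vs large >= 2) x 2 (task)
design the report is regressed on the true auditory and visual counts with
an intercept -- response bias should not contaminate the slopes -- and
`w_AV = atan2(beta_V, beta_A)` in
degrees, kept in [-180, 180) so anticorrelations remain visible.
Model-predicted `w_AV` uses the mode of the Gaussian-KDE-smoothed
distribution of the final estimate over 1e4 fresh simulations per condition.

Factorial inference uses a likelihood-ratio statistic from von Mises
mean-direction models with a single ML concentration per hypothesis
(A1-inverse approximation from the mean resultant).  The cited circular
ANOVA's exact likelihood is not reproduced in the source description, so the
concrete models are ours and are flagged in the test metadata
(`concentration: common-kappa`):

- main effect of factor F: two means by the levels of F vs one grand mean;
- interaction: four cell means vs the additive model
  mu_jk = mu + a_j + b_k (mod 2 pi).  Profiling mu and a analytically
  reduces the additive ML to a 1-D maximisation over b, solved on a 720-point
  grid (180 points in the calibration suites; the statistic is computed
  identically for observed and permuted data, so the resolution does not
  bias the test).

Randomization schemes are within-participant throughout: main effects
permute the tested factor's labels within the levels of the other factor;
the interaction exchanges the simple-effect pairs {(A,small),(V,large)} and
{(A,large),(V,small)}.  One-sample questions use sign flips of the signed
circular distances from the test angle with the mean distance as statistic.
All p-values carry the plus-one correction.  Circular means are reported
with bootstrap percentile CIs (1000 resamples, 68% by default), formed on
wrapped deviations from the full-sample mean so the interval behaves across
the wrap.

## Decoding and representational similarity

Patterns are 20 ms bins of multichannel activity, within-bin samples
concatenated over channels (64 channels x 4 samples = 256 features at
200 Hz) and z-scored per feature per bin; numerically zero-variance features
are set to zero rather than dropped, keeping dimensionality constant across
folds.  Linear nu-SVR decodes stimulus number (labels recoded to
{-1, -0.33, 0.33, 1}) trained on audiovisually congruent trials of all but
one run -- pooled over report tasks by default, per-task training behind a
flag -- with a nested grid search C in {0.1, 1, 10} x nu in {0.2, 0.5, 0.8}
(3-fold grouped by run; the source names the tuned parameters but not their
values).  Predictions for the held-out run are z-scored within run.
Accuracy is the Fisher-z Pearson correlation between true and decoded
number on congruent trials; group inference is a one-sided sign-flip cluster
test.  The neural `w_AV` applies the cell regressions to decoded estimates
per time-bin; its factorial tests are cluster-corrected over time with the
LRTS as the cluster-forming statistic (threshold 2), the cell randomization
drawn once per participant and applied across all bins to preserve temporal
dependence.

Model RDMs are pairwise absolute differences of a per-condition summary of
one internal estimate across the 32 conditions; the behavioural RDM uses
per-condition mean reports.  Neural RDMs are Mahalanobis distances between
condition-mean patterns under the covariance of within-condition residuals,
pooled across conditions within a time-bin (a per-condition covariance is
not identifiable at ~40 trials/condition) and regularised by Ledoit-Wolf
shrinkage -- 256 features against a few hundred trials make the sample
covariance singular.  A fixed covariance can be supplied instead; note the
self-estimated covariance makes distances invariant to global pattern
rescaling.  RDM agreement is Spearman's rank correlation of upper triangles;
constant RDMs are flagged and skipped.  Per-estimate evidences use
BIC = n log(1 - rho^2) + log(n) (log evidence -BIC/2) and feed the same
protected-exceedance machinery per time-bin; the posterior-probability RDM
joins the correlation analyses but not the four-way numeric exceedance.

## Prestimulus oscillations

Morlet wavelets (6-80 Hz in 2 Hz steps, cycles linear from 5 to 13,
via `mne.time_frequency.tfr_array_morlet`) yield single-trial power and
phase, averaged over a configurable occipital set (default O1, O2, Oz, PO3,
POz, PO4), downsampled to 50 Hz on [-0.5, +0.1] s.  Multi-channel phase is
reduced by the circular mean of per-channel unit phasors (the source leaves
this open; the alternative -- the angle of the complex channel mean --
weights channels by amplitude).  Trials are ranked into 10 near-equal
deciles of power (or phase; the rank construction realises circular deciles
whose boundaries start at -pi) separately within each of the 32 conditions
before pooling, and `p_common` (or `sigma_V`) is refitted per decile.
Power profiles correlate with decile-mean power (Pearson, Fisher z,
two-sided sign-flip cluster tests per band: alpha 8-12, beta 14-28, gamma
30-80 Hz); phase profiles use the circular-linear correlation with a
within-participant shuffle percentile (unbiased at 50% under independence)
and a one-sided group cluster test on percentile - 50.

The sinusoidal phase models regress the decile profile of `p_common` on
sin/cos of the decile-mean phase, either per time point or constrained to a
10 Hz carrier over [-280, -80] ms (argument 2 pi F t - Phi(dec, t), t = 0 at
the first analysed sample -- the origin convention only rotates the fitted
phase angle and is recorded here).  The constrained fit on the 10 x 11 grid
tests F with df (2, 107).  Phase-profile alignment circularly shifts each
participant's decile axis so the predicted peak at the reference time
(-160 ms) lands on the group peak; non-unique peaks take the first maximum.

Stimulus history classifies the predecessor at orders 1-5 as small/large
disparity within runs only -- the first trials of a run have no predecessor,
avoiding inter-run contamination -- refits `p_common` per class and order,
and tests the 2 x 5 profile with a within-subject ANOVA
(Greenhouse-Geisser-corrected, implemented here and cross-checked against
pingouin) plus per-order paired t tests.  Moderation re-runs the decile
correlation separately per order-1 history class and cluster-tests the
Fisher-z difference; the mediation check cluster-tests the raw power
difference between classes.

## The synthetic generator

`synthetic_data` emulates exactly the structure the analyses assume: 23
participants by default, 8 audiovisual runs (4 auditory-, 4 visual-report,
alternating), 16 conditions x 10 trials per run in randomized order, plus
unisensory runs only for the ERP fixture.  Observer parameters per
participant are drawn around the group means (p_common 0.42, mu_P 2.26,
sigma_P 2.34, sigma_A 0.53, sigma_V 1.11) with between-participant SDs
(0.15, 0.5, 0.7, 0.12, 0.4) chosen to match the scale of the reported
group SEMs, clipped to valid ranges.  Responses come from the observer
model itself; when an oscillation spec is supplied the trial-wise effective
causal prior is logistic in standardised predictors,

    logit(p_eff) = logit(p_common) + b_alpha z(log alpha power)
                   + b_gamma z(log gamma power)
                   + b_phase cos(phase - phase_ref) + history drive,

which keeps the prior in (0, 1) and makes coefficients log-odds per SD.
Pattern fixtures are rank-one linear encodings of chosen internal estimates
with per-bin weights, unit random loadings, optional run-gain jitter and
i.i.d. Gaussian noise.  Oscillation fixtures place each trial's alpha/gamma
amplitude and alpha phase into band-limited bumps on a multiplicative-noise
1/f background, with phase advancing at each row's frequency so the linked
(10 Hz, -200 ms) point reproduces the state that drove behaviour exactly.

What the generator does not emulate: volume conduction and channel
covariance structure, non-Gaussian EEG noise, artefacts, autocorrelated
background oscillations, reaction times, or any biophysical forward model.
Passing tests therefore certify the statistical machinery and its
calibration under the model's own assumptions, not robustness to real EEG
noise.

## Problem sizes and calibration choices

The validation suites run at the design's behavioural scale (1280 trials per
participant) and reduced group/grid sizes chosen for a serial desk run:
20 simulated participants for parameter recovery; 20 simulated experiments
(n = 23 each) for the w_AV interaction signature; 200 null simulations with
1000 randomizations each for every randomization engine (circular LRTS,
1-D/2-D cluster tests, decile-correlation and moderation tests), asserting
family-wise error <= 0.07 at alpha = 0.05; 12 participants x 32 features x
6 bins for the decoding/RSA signatures; 10-15 participants for the
oscillation-linkage recoveries.  Null calibrations of the oscillation tests
hold behaviour fixed and redraw the (independent) oscillatory metric each
simulation, which is exactly the null hypothesis those tests address.  The
acceptance script uses 12 behavioural, 6 neural and 10 oscillation
participants and 2000 randomizations.

## Known limitations

- The simulated likelihood inherits Monte-Carlo granularity; with common
  random numbers the objective is deterministic but its minimiser shifts by
  O(1/sqrt(n_samples)) relative to the exact ML.
- The LRTS small-sample null is taken entirely from randomization; no
  asymptotic chi-square calibration is attempted (the concentration
  estimate uses the A1-inverse approximation).
- Protected exceedance probabilities use the standard variational scheme;
  for very small groups the BOR dominates and pEPs shrink to uniform by
  construction.
- `decode_number` retrains one SVR grid per (bin, fold); run-level gain
  artefacts beyond a scalar jitter are not modelled in the fixtures.
- The RSA noise covariance is pooled within time-bin across conditions; a
  crossnobis variant is out of scope.
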