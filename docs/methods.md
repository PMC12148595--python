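# Methods note

This note records the generative models, the statistical procedures, the
default parameter values and why they were chosen, and the numerical
design decisions.  All quantities below are properties of the synthetic
generator and of the estimators; no empirical claims about real subjects
are made.

## Design

Eight conditions cross experience (high/low "being moved": H/L), modality
(perception/imagery: P/I) and stimulus type (art/face: A/F), in the
canonical order `HPA, LPA, HPF, LPF, HIA, LIA, HIF, LIF`.  The default
study size is 34 subjects × 40 stimuli (20 artworks, 20 faces), each
stimulus rated once per modality on three 7-point dimensions (pleasure,
beauty, being moved), with a 7-point vividness report on imagery trials.

## Ratings generator (`imaes.simulate.generate_ratings`)

Ratings arise from a cumulative-probit latent structure.  For subject *s*,
stimulus *i*, dimension *d*:

- perception latent mean: `mu = u_s + u_i + beta_type * face(i)`,
- imagery latent mean: `mu' = mu + beta_modality + kappa * (7 - v)/6 * eps`,
  where `v` is the trial's vividness and `eps ~ N(0,1)`,
- observed category: latent mean plus unit normal noise, cut at ordered
  thresholds `tau`.

Random intercepts `u_s ~ N(0, sd_subject^2)` and `u_i ~ N(0, sd_stimulus^2)`
are drawn independently per dimension; vividness is drawn once per
(subject, stimulus) and shared across the three dimensions, since it
describes the image, not the judgment.

Defaults and rationale:

- `beta_modality = -0.29`, `beta_type = -0.56`: standardized latent effects
  of plausible magnitude for "small" and "medium" condition differences on
  ordinal scales; imagery slightly less moving than perception, faces less
  than art.
- `thresholds = (-1.5, -0.9, -0.3, 0.3, 0.9, 1.5)`: symmetric, equally
  spaced cutpoints so the 7 categories are all used without extreme
  sparsity.
- `sd_subject = 0.5`, `sd_stimulus = 0.3`: between-subject heterogeneity
  larger than between-stimulus, as is typical for affect ratings.
- `vividness_probs = (0.02, 0.04, 0.08, 0.16, 0.25, 0.25, 0.20)`: a
  left-skewed distribution — most imagery reports are fairly vivid, with a
  thin low-vividness tail.
- `kappa = 3.6`: the vividness-to-noise coupling.  Calibrated once against
  a latent-scale oracle so that the standardized slope of the dissimilarity
  score on vividness is about −0.27 (grid: kappa 3.0 → −0.24, 3.5 → −0.26,
  4.0 → −0.28); `kappa = 0` switches the coupling off.
- `missing_rate = 0`: optional missing-completely-at-random dropout for
  testing the complete-case filter.

Realism and limits: the generator produces exchangeable stimuli within
type, no serial order effects, no response styles (e.g. scale-end
avoidance), and missingness only of the MCAR kind.  It is a validation
instrument, not a behavioral model of record.

## Pattern generator (`imaes.simulate.generate_patterns`)

A target condition geometry is specified as weights `(w_mod, w_exp,
w_type)` on the three binary factors (or as the constant "independent"
geometry).  The planted RDM is embedded exactly by classical
multidimensional scaling (double-centering, eigendecomposition), scaled so
the mean squared condition norm equals the channel count, and mapped into
`n_channels = 200` channels through a deterministic orthonormal cosine
basis whose vectors are orthogonal to the constant channel.  Because the
embedded means have zero channel-mean and equal norms, the z-scoring
applied when computing neural RDMs preserves the planted geometry exactly
(verified to floating-point accuracy in the tests).

Per-subject variation has two parts:

- `subject_sd = 0.15`: low-rank jitter of the condition coordinates in the
  embedding space, giving each subject an idiosyncratic but structured
  geometry;
- `noise_het = 1.0`: log-normal between-subject spread of the measurement
  noise SD, normalized so the *expected squared* noise SD stays at
  `noise_sd^2 = 0.16` (`noise_sd = 0.4`, "moderate noise": recovery of the
  generating model is expected by design at 30 subjects).

Both are needed for a realistic noise ceiling: squared-distance RDMs carry
a noise-dependent additive offset, and if every subject had identical
means and identical noise, that offset would be a deterministic bias with
almost no between-subject variance, making every model score
*significantly* different from the ceiling no matter how good the model
is.  Heterogeneous subjects are the realistic case and the one in which
ceiling comparisons are meaningful.

## Behavioral statistics

- **Dissimilarity score** (`behavior.dissimilarity_score`): per subject and
  stimulus, the sum over the three dimensions of squared
  perception-minus-imagery differences; range 0–108.
- **Cumulative probit** (`bayes.fit_cumulative_probit`): fixed effects for
  modality and stimulus type, random intercepts for subject and stimulus,
  ordered thresholds.  Priors: `N(0,1)` on the betas, `student_t(3, 0,
  2.5)` on thresholds, `half-t(3, 0, 2.5)` on intercept SDs.
- **Vividness regression** (`bayes.fit_vividness_regression`): z-scored
  score on z-scored vividness with Student-t residuals (degrees of freedom
  estimated, `gamma(2, 0.1)` prior truncated at 1) and subject intercepts.
- **ROPE Bayes factor** (`bayes.rope_bayes_factor`): BF01 as the posterior
  odds of the region of practical equivalence [−0.1, 0.1] over the prior
  odds; prior mass computed analytically, posterior mass from the draws
  (or analytically for a frozen distribution).

## Sampler

No general-purpose probabilistic-programming stack is assumed; the models
are fitted by a custom adaptive random-walk Metropolis-within-Gibbs:

- conditionally independent blocks (all subject intercepts, all stimulus
  intercepts, alternating odd/even thresholds) are updated jointly with
  vectorized likelihood deltas;
- proposal scales adapt by Robbins-Monro during warmup toward 0.44
  acceptance, then freeze, keeping the chain Markovian;
- three likelihood-invariant translation moves break the posterior ridges
  between `beta_type` and the face-stimulus intercepts, and between the
  thresholds and each intercept block's mean — without them `beta_type`
  mixes poorly;
- the vividness model uses a non-centered subject-intercept
  parametrization (`u = sigma_u * z`) to avoid the funnel at
  `sigma_u ≈ 0`, and rejects proposals below `sigma = 1e-3` to keep the
  posterior proper on degenerate data;
- convergence is summarized by split-Rhat and bulk effective sample size
  (via `arviz`) over *all* stored parameters; `converged` means every
  Rhat < 1.05.  Default run: 4 chains × (2000 warmup + 2000 kept).

## RSA statistics

- **Neural RDMs**: squared Euclidean distances between z-scored condition
  patterns (z-scoring per channel across conditions; population SD).
- **Whitened cosine**: `s = d1' V^-1 d2 / sqrt((d1' V^-1 d1)(d2' V^-1 d2))`
  with `V` either the identity (plain cosine) or the distance-covariance
  proxy `V ∝ (C C') ∘ (C C')` built from the 28 × 8 pairwise contrast
  matrix, normalized to unit trace.  The proxy captures the correlation
  structure distances share through common conditions.
- **Noise ceiling**: upper = mean cosine of each subject RDM with the
  grand-mean RDM; lower = mean leave-one-out cosine; per-subject
  leave-one-out values feed the ceiling tests.
- **Model comparison** (`inference.compare_models`): paired two-tailed
  t-tests on per-subject score differences for all model pairs with
  Benjamini–Hochberg FDR control (q < 0.01); one-sample t against zero; a
  paired t against the lower ceiling, Bonferroni-corrected over models,
  with a model flagged `below_ceiling` only when significantly *below*.
  Exact ties yield t = 0, p = 1 rather than NaN.
- **Uncertainty**: subjects are resampled with replacement (default 2000
  draws, seeded); percentile 95% intervals, bootstrap SD as the SEM.

## Numerical and testing choices

- All randomness flows through `numpy` `SeedSequence` children keyed by the
  design seed and a stage constant, so ratings and patterns are
  independently reproducible.
- Validation problem sizes in the test suite (e.g. 30 subjects, 200
  channels, 100 recovery replicates; 20 ordinal-recovery replicates at
  34 × 40) are this package's own choice of a desk-scale budget: large
  enough for the planted effects to be decisively detectable, small enough
  to run in minutes on one CPU.
- Ordinal-effect recovery is assessed with the vividness coupling switched
  off (`kappa = 0`), because the probit model does not include
  heteroscedastic imagery noise; with coupling on, the modality effect is
  attenuated by design, which is a model-misspecification fact, not an
  estimator defect.

## Limitations

- The distance-covariance whitener is a structural proxy, not an estimate
  from data; it ignores condition-specific noise levels.
- The sampler is tuned for these two models; it is not a general inference
  engine, and very small or degenerate datasets may need longer chains for
  Rhat < 1.05.
- The generator plants geometry at the level of condition means; it does
  not simulate trial-level fMRI time series, GLM estimation, or spatial
  noise correlations.
- Squared-distance RDMs without cross-validation carry a positive noise
  offset; the package compensates by comparing *shapes* (cosines) and by
  realistic between-subject heterogeneity, not by unbiased distance
  estimators such as crossnobis.
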