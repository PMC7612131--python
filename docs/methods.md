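# Methods

This note documents the models behind each stage, the parameter defaults
and why they were chosen, the numerical conventions, and what the
synthetic generators do and do not emulate.

## Epoch grid and ERP scoring

Epochs live on a fixed response-locked grid: −400 ms to 500 ms at 250 Hz,
inclusive endpoints, 226 samples 4 ms apart. All windows are inclusive at
both ends: the baseline window −400…−200 ms spans 51 samples, the peak
search window −20…120 ms spans 36 samples, and the adaptive-mean window of
±40 ms around the peak spans 21 samples.

Scoring conventions, all configurable in `ScoringConfig`:

- **Baseline**: each epoch's own baseline-window mean is subtracted from
  every sample of that epoch.
- **Rejection** is applied after baseline correction, with a strict
  comparator: an epoch is rejected only when |amplitude| *exceeds* 50 μV at
  some sample; a sample exactly at 50.0 μV is kept. If every epoch of a
  subject is rejected the scorer raises, and the subject is handled by the
  screening stage.
- **Adaptive mean**: minimum sample within the search window (earliest
  latency wins ties), then the mean over the 21 samples at peak ±40 ms. On
  the standard grid this window is always interior to the epoch; in the
  general case it is clipped to the epoch bounds.
- **Trough-to-peak** is reported as (search-window minimum) − (maximum over
  [−100 ms, trough latency]); the preceding-positivity window start is a
  package convention, exposed as `trough_to_peak_pre_ms`.
- **Residualised ERN** uses ordinary least squares of ERN on CRN with
  intercept across subjects; a zero-variance CRN degenerates to the
  centered ERN with a warning.
- **Split-half reliability** splits by epoch index (even indices vs odd;
  an odd count leaves the extra epoch in the even half), scores each
  half-average, Pearson-correlates across subjects, and applies the
  Spearman–Brown projection 2r/(1+r). Pearson, not rank, correlation is
  used throughout.

## Synthetic EEG generator

Each trial of subject *s* in condition *c* is

    x(t) = (A·g + ρ·D)·b(t − j) − D·b_n(t − j) + ε(t)

- `b` — half-cosine bump, unit peak, width 100 ms (full width), centred at
  37.61 ms, the grand-average latency of the most negative error-trial
  peak. The width default keeps the ±40 ms averaging window inside the
  component.
- `A` — the subject's true amplitude, drawn from N(−3.11, 2.79²) μV for
  error trials and N(0.30, 1.89²) μV for correct trials (the reported
  population values for the adaptive-mean ERN and CRN).
- `g` — calibrated gain: the adaptive-mean score of the noiseless unit
  component equals exactly one per μV of requested amplitude, so the
  noiseless round trip score(generate(A)) = A holds to machine precision.
- `D·(ρ·b − b_n)` — the **morphology anchor**: a narrow half-cosine notch
  `b_n` (width 40 ms, same centre, depth D = 28 μV) plus a compensating
  multiple of the wide bump. The compensation ratio ρ is chosen so the
  anchor contributes exactly zero to the windowed mean around the detected
  peak (computed against the jitter-blurred kernels, and reducing to an
  exact zero at zero jitter). The anchor emulates the morphology of real
  response-locked waveforms, where the negativity is a dip relative to
  surrounding positivity: it pins the detected negative peak at the
  component latency for positive as well as negative amplitudes, which is
  what makes a +0.3 μV CRN recoverable by a minimum-picking estimator. D
  is large enough to dominate any |A| ≤ 10 μV and small enough that clean
  epochs stay far from the ±50 μV rejection bound.
- `j` — per-trial latency jitter, N(0, 10 ms²). The magnitude is not
  reported for the original data; 10 ms is a modelling choice exposed in
  the config. Jitter blurs the subject-average component and attenuates
  recovered amplitudes by roughly 3% (e.g. ≈ +0.10 μV on a −3.11 μV ERN);
  the generator deliberately does **not** compensate this, so recovery is
  exactly unbiased at zero jitter and carries a small, bounded,
  documented attenuation otherwise. Peak picking on noisy averages adds a
  further small negative bias that shrinks with epoch count.
- `ε` — i.i.d. Gaussian sample noise, default SD 10 μV. White noise is a
  simplification (no 1/f structure, no artifact classes, no channel
  covariance); it is sufficient for the estimator properties under test.
  At the default level the ±50 μV rejection removes a fraction of a
  percent of epochs, the same order as reported for the real data.

Per-subject epoch counts are gamma-distributed, rounded, and floored at 9
(the minimum retained count in the study): error trials mean 51.88, SD
33.09; correct trials mean 404, SD 58.78.

A single virtual frontocentral channel is simulated. Multi-electrode
variants would be independent replicates sharing the true score; they are
not needed by any analysis here and are out of scope.

### Reliability-targeted noise

`derive_noise_for_reliability(target_r, n_epochs, between_sd)` inverts the
classical reliability model: it finds the per-epoch sample-noise SD σ such
that r = σ_b²/(σ_b² + v_half) equals the Spearman–Brown-inverted target,
where v_half — the score-noise variance of the adaptive mean applied to an
(n/2)-epoch average — is estimated by a small internal Monte-Carlo (600
replicates, common random numbers), because peak picking makes the
estimator nonlinear. v_half is very nearly proportional to σ², so three
multiplicative updates converge. For the reported ERN reliability (0.90 at
52 epochs, between-subject SD 2.79 μV) the derived σ is ≈ 26 μV per
sample.

The reliability study path scores halves without threshold rejection: the
derived noise is a score-level abstraction of total trial-to-trial
variability, not raw-EEG artifact amplitude, and white noise of that
magnitude would trip a threshold designed for structured low-frequency
artifacts. Latency jitter is likewise held at zero in this path — the
reliability target concerns noise, and the supplied between-subject SD is
the observed (already attenuated) score SD.

## Flanker behaviour generator

Error probability depends on congruency only (defaults 3.6% congruent,
15.6% incongruent); 2.4% of trials are random lapses; response times are
shifted log-normal (shift 100 ms — the positive skew typical of RT data)
with means 283 ms (correct) and 212 ms (error), SD 67.6 ms, a ±31 ms
congruency shift and +20 ms after a committed error within the same
block. RTs beyond the 1050 ms deadline become misses. Defaults mimic the
reported cohort means; only the *signs* of the four behavioural contrasts
(more incongruent errors, slower incongruent RTs, faster errors, post-error
slowing) are treated as recoverable claims, not the exact means, since the
generator's additive structure is a simplification. Congruent/incongruent
order is a uniform shuffle within block (the original randomisation
constraints are not reported). End-of-block feedback: "faster" when
missed > 25% or accuracy > 90% (speed message wins when both speed and
accuracy rules hold, mirroring the stated order), else "more accurate"
when accuracy < 75%, else "great job".

## Screening

Rules use the printed strict comparators — missed trials > 96, accuracy
< 0.55, catch answer ≠ "A little", error-epoch survival < 0.95 under the
±50 μV criterion — evaluated in the published order with each excluded
subject attributed to the first rule it fails. Accuracy is computed over
responded (non-missed) trials. Data corruption is an input flag, not
detected from raw files. Post-error/post-correct RT strata condition on
the previous non-missed trial's correctness within the same block; the
first trial of a block and trials following a missed trial are dropped
from those strata (no inter-block carryover).

## Questionnaire cohort generator and phenotyping

Three latent factors with unit variance and correlations 0.36 (AD–CIT),
0.39 (AD–SW), 0.33 (CIT–SW) — inside the reported 0.33–0.39 band. Item
propensity = 0.6 × (dominant factor) + N(0, 0.8²), standardised and
discretised at thresholds (−1, 0, 1) for 4-level items (or evenly spaced
normal quantiles otherwise). The manifest uses the published instrument
lengths, which sum to 209 (AUDIT 10, AES 18, SDS 20, EAT-26 26, BIS-11
30, OCI-R 18, SSMS 43, LSAS 24, STAI-T 20); OCI-R is coded 0–4 per item
and STAI 1–4 so totals land on the instruments' native ranges and the
clinical flags (OCI-R ≥ 21; STAI > 41, strict) are meaningful. The
reverse-scoring pattern (every 5th AES/BIS-11/STAI item) and the factor
assignment of instruments are synthetic conventions; no licensed item
content is reproduced.

Dimension projection is a weighted sum of the 209 **raw** item responses
under a fixed 209 × 3 weight matrix, then z-scored across the analysed
cohort. The published weight matrix is not reproduced; the package ships a
loader for a user-supplied CSV and a synthetic default equal to the
generator's loadings (clearly labelled non-canonical). Regression-based
factor scoring is a possible alternative; the weighted sum is the
implemented default.

## Regression battery and power

OLS with intercept and conventional (non-robust) standard errors, matching
`lm()`-style models. Predictors and continuous covariates are z-scored
(population SD) over the analysed subjects, so a single-predictor beta is
in μV per SD and equals Pearson r × SD(outcome). Nine questionnaire models
are fitted separately (the scales are highly intercorrelated); the three
dimensions enter one joint model. The exact Bonferroni threshold α/9 =
0.00556 is reported alongside the conventional 0.005 threshold; both
appear in the run output because which was decisive is ambiguous in
practice. The power routine uses the Fisher-z approximation with ceiling
and the +3 correction term, N = ⌈((z₁₋α/₂ + z_power)/atanh r)² + 3⌉, which
gives N = 155 for r = 0.32 at α = 0.005 and 90% power, and whose returned
N achieves the requested power in direct simulation.

## Two-step task

Canonical hybrid agent: SARSA(λ) model-free stage-1 values (stage-2
prediction error propagated with eligibility λ), model-based values from
the known transition matrix (p_common = 0.7) times the best stage-2
value, mixed by w_mb, softmax choice with inverse temperatures β₁, β₂ and
a first-stage perseveration bonus. Reward probabilities follow Gaussian
walks (SD 0.025) clipped to [0.25, 0.75] — canonical values for the task;
the original description says only that they drifted slowly. Default 200
trials per subject (the exact count is not printed; configurable).

Stay analysis: records start at trial 2; stay = repeated first-stage
choice; previous reward and transition are effect-coded ±1 (dummy coding
is an option), so the reward × transition coefficient directly indexes
model-based control and flips sign exactly under transition-recoding. The
pooled model without dimensions absorbs subject heterogeneity with
per-subject intercepts (fixed effects); with dimensions it is a single
pooled logistic adding each z-scored dimension and its interactions with
the three base terms, the headline association being each dimension ×
reward × transition coefficient. The original group-level model may have
used random effects; the linear-predictor builder is isolated so a
mixed-model backend could be swapped in, and only sign/recovery
properties, not coefficient magnitudes, are treated as testable claims.
Perfect separation is caught, flagged, and refitted with BFGS with a
warning. Cohort couplings set w_mb = logistic(base + slope·z(dimension)).

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to keep Monte-Carlo error
comfortably inside each asserted tolerance: amplitude recovery uses 10
replicate cohorts of 196 subjects (grand-mean sampling SE ≈ 0.06 μV for
the ERN, 0.04 μV for the CRN); reliability checks average two 196-subject
forward simulations; the null-calibration study uses 2000 cohorts of 196
subjects at the score level (9 tests each), with a cluster-robust standard
error because tests within a cohort share the outcome draw; the
model-based coupling recovery uses 20 replicates of 250 agents × 150
trials at slope −0.8. The acceptance script uses 8 replicate cohorts for
the CRN grand mean and 3 for reliability.

## Known limitations

- White epoch noise and a single channel: no 1/f spectrum, ocular or line
  artifacts, or spatial structure; conclusions about artifact-rejection
  behaviour on real EEG do not follow.
- The behaviour generator imposes effects additively rather than deriving
  them from a process model (no drift-diffusion dynamics), so RT
  distributions match in location/scale/skew, not mechanism.
- Ordinal items share one discretisation scheme and a block-diagonal
  loading structure; real instruments have cross-loadings and varied
  response formats.
- The dimension weight matrix is synthetic by default; analyses of real
  data require the user-supplied published weights.
- The stay-probability model is fixed-effects pooled, not mixed-effects;
  per-subject indices from short runs are noisy and occasionally
  separation-flagged.
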