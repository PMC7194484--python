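# Methods

This note records the models, algorithms, numerical choices and known
limitations of `latertwin`, in the order data flow through the package.

## 1. fTCD signal pipeline

**Input.** A recording is two velocity channels (left/right middle
cerebral artery, cm/s) on a strictly uniform time grid, with marker
samples at each "cue to speak" and an optional behavioural validity flag
per trial. The delimited-text reader infers the sample rate from the
time column and cross-checks it against configuration.

**Dropout.** Velocity is physiologically strictly positive, so a sample
≤ 0 (or missing) is treated as probe dropout. A single isolated dropout
is repaired with the mean of its flanking samples. Runs of two or more
samples (and dropouts at the recording edges) are bridged by linear
interpolation only to keep integration finite; their intervals are
recorded and any trial whose epoch overlaps one is later rejected with
reason `prolonged_dropout`.

**Heart-cycle integration.** Cardiac pulsatility dominates the raw
trace. Beat onsets are detected as peaks of the summed left+right
channel with a minimum inter-beat interval of 0.33 s (≤ 180 bpm — safe
for child heart rates, and a single robust knob), then refined to
sub-sample position with a three-point parabola so that cycle boundaries
are not snapped to the grid. Each cycle is replaced by its time-weighted
mean — the trapezoid integral of the linearly interpolated channel
between (possibly fractional) onsets divided by the cycle length — and
the per-cycle means, anchored at cycle midpoints, are linearly
interpolated back onto the original grid (clamped beyond the first/last
cycle). Sub-sample boundaries matter: with integer-sample cycles a
pulse period that is incommensurate with the sample grid leaves a
residual ripple of up to ~1%; with fractional boundaries the residual on
a pure sinusoid is far below the 0.5% contract the tests assert.
Integration preserves each channel's overall mean to within 0.5%.

**Normalisation.** Each channel is rescaled so its recording-wide mean
is 100. Values are thereafter percentages of mean flow, which removes
probe gain entirely: scaling both raw channels by any γ > 0 leaves every
downstream number unchanged (asserted as a property test).

**Epoching and rejection.** One epoch per marker, spanning −12 s to
+18 s around the cue (covers the 12 s silent-viewing and 10 s speaking
periods with margin; the study's exact window is not public, so this is
a declared default, configurable and recorded in output metadata).
Rejection reasons, in the order checked: `prolonged_dropout`;
`artifact` — any normalized sample outside [60, 140]% (standard fTCD
practice; also used when the epoch window runs off the recording edge,
with a warning); `behaviour` — the examiner's validity flag. Accepted
epochs are baseline-corrected per channel by subtracting the channel
mean over −5 to 0 s (the late silent-viewing interval), making the
baseline mean exactly zero.

**Laterality indices.** The difference wave is left − right in
percentage points (positive = left-lateralised). Per accepted trial:

* mean-based LI — mean of the difference over the period of interest
  (POI), 4–14 s after the cue;
* peak-based LI — mean over ±1 s around the sample of largest absolute
  difference within the POI (a 2 s window, truncated at the POI edges;
  exact ties broken to the earliest sample for determinism).

The subject LI is the mean of accepted trial LIs. Because trial LIs are
linear in the difference wave, this equals the POI mean of the averaged
difference waveform whenever the same trials enter both computations;
the package computes per-trial-then-average, which also yields the
trial-to-trial SE. The SE is the sample SD of trial LIs over √n, and
the 95% CI uses the Student-t quantile with n−1 df (trial counts are
12–30; a normal quantile would be anticonservative). Category: `left`
if the mean-based CI lies above 0, `right` if below, else `bilateral`.
The binary typical/atypical code follows the peak-based CI: `typical`
only when that interval lies entirely above zero. Mean left/right flow
per subject is the baseline-corrected normalized channel mean over the
POI, averaged across accepted trials — i.e. the task-evoked flow change,
the quantity on which a shared-environment (CE) analysis is meaningful
after per-recording normalisation.

**Exclusions and reliability.** Subjects with fewer than 12 accepted
trials are excluded (`too_few_trials`); with ≤ 1 trial the SE is
undefined and the subject is excluded. Cohort-level outlier exclusion is
a single pass (not iterated): subjects more than 5 SD from the mean of
currently non-excluded LIs are flagged `outlier_5sd`; propagating the
exclusion to the cotwin is done by the twin-table builder, which drops
incomplete pairs listwise per phenotype. Split-half reliability is the
Pearson correlation between mean LIs of odd- and even-numbered accepted
trials (presentation order, 1st/3rd/… vs 2nd/4th/…); the Spearman–Brown
full-length value 2r/(1+r) is reported alongside, never substituted.

## 2. Handedness scoring

EHI: 10 demonstrated actions; right = 1, either = 0.5, left = 0, range
0–10. QHP: 21 card trials (3 per each of 7 positions); right = 2,
transfer = 1, left = 0, range 0–42. The position layout is validated but
does not enter the score. A missing item prorates the score to the full
scale and sets a flag — prorating preserves the scale range while
marking the added uncertainty.

## 3. Twin variance decomposition

Pairs are modelled as bivariate normal with a single common mean and
variance across twin order, zygosity and sex (an optional OLS
residualisation for age/sex is available as a pre-step). The within-pair
correlation is k·a² + c² with k = 1 (MZ) or 0.5 (DZ). Free proportions
are box-constrained to [0, 1] (ACE uses the substitution a² = u₁,
c² = (1−u₁)·u₂ so the unit-sum constraint is a box), variance is
optimised on the log scale, and the likelihood is evaluated from
per-group sufficient statistics so a fit costs microseconds per
evaluation. Optimisation is L-BFGS-B from a moment-based start
(Falconer estimates of the group correlations) plus jittered restarts
with fixed seeds — boundary solutions (a² = 0) are common in laterality
data and restarts guard against poor starts. Estimates within 10⁻⁶ of
the zero boundary are reported as exactly 0 and the log-likelihood is
re-evaluated at the reported values, so nested-model comparisons at the
boundary give a chi-square of exactly 0.

Profile-likelihood intervals solve 2·Δloglik = χ²₁(0.95) by bisection on
each side of the estimate, truncated to [0, 1]; the lower bound is 0
whenever the boundary lies inside the interval. Model comparison uses
the standard χ²(df) upper tail; because a² = 0 sits on the parameter
boundary, the 50:50 χ²(0):χ²(1) mixture reference is available behind a
flag (df = 1 only) and roughly halves the p-value — the two are never
silently interchanged.

The ML intraclass pair correlation fits (μ, v, r) by the same machinery
with r on a tanh scale and profiles r for its CI; labelled double-entry
Pearson and Spearman variants are returned alongside because published
twin correlations may use either convention.

## 4. Trivariate Cholesky AE model

Three phenotypes per twin (fixed order EHI, QHP, LI) follow
y = μ + L_A f_A + L_E f_E with lower-triangular 3×3 paths; within-twin
covariance W = L_A L_Aᵀ + L_E L_Eᵀ, cross-twin k·L_A L_Aᵀ. The
triangular parameterisation keeps the implied 6×6 covariance positive
semi-definite for every parameter value, so no constraints are needed
during optimisation; path signs are normalised afterwards (columns
flipped so diagonals ≥ 0 — L and L·D imply the same covariance).
Missing phenotypes are handled by full-information ML: rows are grouped
by missingness pattern and each pattern's observed block is evaluated
vectorised. Reported estimates are unsquared standardized paths
(L rows divided by √diag(W)), which by construction satisfy
Σ paths_A² + Σ paths_E² = 1 per trait; their SEs come from the observed
information matrix (numerical Hessian) pushed through the
standardisation map by the delta method. With A ≈ 0 the genetic paths
are weakly identified (their signs are arbitrary and SEs large); the
specific-LI genetic path in particular can sit at 0 with a wide SE.

## 5. Extremes analysis

Probands are all twins scoring past a caller-supplied cutoff
(documented defaults: EHI ≤ 4/10, QHP ≤ 14/42, LI < 0; the report
always echoes the cutoff used). Under the default double-entry
convention a pair where both twins qualify contributes both members as
probands, each bringing the other as cotwin. MZ and DZ cotwin scores are
compared with Welch's t-test (Satterthwaite df). Caveat: double entry
lets a both-extreme pair contribute two correlated cotwin observations,
which violates the independence assumption of the t-test and inflates
its nominal size (empirically to ~0.10 at a low cutoff with 100 pairs
per group under a² = 0); the single-entry variant (one proband per
pair, behind a flag) is calibrated at the nominal 5% and is what the
calibration tests assert. Empty proband groups raise, never a silent
p-value.

## 6. Power

Phenotypes are standardised to unit variance — power depends only on
the proportions and the group sizes. The analytic method builds the
population MZ/DZ correlation matrices implied by (a², e² = 1 − a²),
fits the false E-only model to them by minimising the grouped ML
discrepancy Σ n_g F_g (which lands at unit variance and
λ = −Σ n_g ln(1 − r_g²)), and reads power from the noncentral χ²(1, λ)
tail beyond the central 0.95 quantile. The Monte-Carlo method simulates
cohorts, fits AE and E by ML (the E-model MLE is closed-form) and counts
LRT rejections.

Finite-sample accuracy: the two methods agree within Monte-Carlo error
in the local-alternative regime (hundreds of pairs per group), while at
roughly a hundred pairs per group the analytic value overstates
simulated power by up to about three percentage points — the simulated
LRT is slightly lighter-tailed than its limiting distribution. Both
regimes are asserted in the tests; reported analytic values at study
sizes should be read with that margin in mind.

With the boundary-mixture flag the analytic power is computed for the
constrained statistic [max(0, Z + √λ)]², i.e. Φ(√λ − √c) at the
standard critical value; at a² = 0 this reports α/2 where the standard
convention reports α. The CLI prints the other convention whenever the
two differ by more than 0.01.

## 7. Synthetic data

**Twin phenotypes.** The generative model is the ACE decomposition
itself: per pair, an additive factor correlated 1 (MZ) or 0.5 (DZ), a
shared factor, independent nonshared factors;
y = √a²·A + √c²·C + √e²·E. The optional J-shaped marginal applies the
frozen monotone map 10·Φ(y)^0.25 (versioned constants, so tests are
stable across releases), piling mass at the right-handed end of a
bounded 0–10 scale the way preference inventories do while preserving
rank-based familial structure exactly (Spearman correlations are
invariant under strictly monotone maps).

**fTCD sessions.** A continuous two-channel trace emulating the
animation-description paradigm: cues every 35 s (first at 20 s — the
spacing must exceed the 30 s epoch span, enforced), 25 Hz sampling,
baselines 55/50 cm/s. Components: cardiac cycles with jittered
intervals (95 ± 8 bpm — child range) and a systolic bump made exactly
zero-mean within each cycle's samples, so the generator's stored
per-cycle means are an exact oracle for integration; per-channel
multiplicative AR(1) drift (coefficient 0.995/sample, stationary SD 1%);
2% multiplicative white noise; a gamma-shaped activation (shape 4,
scale 2 s — rising to a peak 6–8 s post-cue and back near baseline by
~17 s, which makes mean- and peak-based LIs genuinely different) scaled
to unit mean over the 4–14 s POI. The left channel gains
+δ/2 percent times the activation and the right −δ/2, on top of a
shared bilateral component; the per-channel gain is centred to zero
recording mean so that after normalisation and baseline correction the
POI-mean difference equals δ exactly in expectation. Injected events
(single-sample dropouts, ≥ 2-sample dropouts, 1.7× amplitude spikes,
behaviourally invalid trials) are drawn per trial with configured
probabilities and logged, making pipeline rejection counts exactly
checkable. All generators are bit-reproducible for a fixed seed.

**What the generators do not emulate.** Real probe artifacts are not
simple amplitude steps; real activation shapes vary within subject;
dropout in real recordings correlates with movement and hence with
behavioural invalidity; heart-rate variability is autocorrelated, not
white. Passing the pipeline tests therefore demonstrates correctness of
the implemented operations on signals with known structure, not
robustness to every failure mode of real paediatric recordings.

## 8. Study runner and problem sizes

`run_study` composes the stages end-to-end on simulated data: a latent
per-subject true LI drawn from the twin model (defaults: a² = 0 for the
laterality trait, population mean 2.5, SD 1.5 percentage points — a
left-biased population in which most subjects are significantly
left-lateralised), one Doppler session per twin pushed through the
pipeline, J-shaped handedness traits (defaults a² = 0.25 and 0.18),
listwise pair exclusions, univariate fits with profile CIs and LRTs for
five phenotypes, the trivariate Cholesky model, extremes t-tests and a
power table, with every output serialised deterministically
(re-running a config byte-reproduces the bundle). Default problem sizes
(65/76 pairs, 24 trials per session) match the laterality subsample;
tests use smaller cohorts chosen to exercise every code path. The
simulation cross-check in the acceptance script uses 2000 replicates
per design, giving a Monte-Carlo SE of about one percentage point.

## 9. Known limitations

* Ordinal/liability-threshold ACE models for the J-shaped handedness
  scores are out of scope; handedness is analysed on the continuous
  scale, which is what the primary published comparisons did, but the
  continuous treatment of a bounded, skewed score is an approximation.
* Sex-limitation and opposite-sex-specific models are not implemented;
  opposite-sex DZ pairs pool with same-sex DZ.
* The univariate means model is fully homogeneous; systematic mean
  differences between groups would be absorbed into the variance.
* The Cholesky model reports Wald-type SEs; profile intervals for path
  parameters are not implemented.
* Full DeFries–Fulker regression (basic/augmented) is not implemented —
  only the proband/cotwin t-test comparison.
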