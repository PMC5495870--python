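# Methods

`balancenet` implements a complete analysis chain for directed cortical
connectivity during a postural perturbation experiment: a subject stands
on a platform that is held stable (BSS, *balancing on a stable surface*)
and released at a known onset into free oscillation (BUS, *balancing on
an unstable surface*), while multi-channel EEG is recorded over repeated
trials.  The chain estimates, per subject, a time-variant multivariate
autoregressive (tvMVAR) model across trials, derives time-variant
generalized partial directed coherence (gPDC), condenses it into
directed networks and node-strength statistics, and decomposes the
group-level connectivity tensor by 4-mode PARAFAC.  Because no public
recording of this experiment exists, the package ships a synthetic-data
generator with planted ground truth; every pipeline property is
validated against that ground truth.

## Synthetic data generator

Neural dynamics are a time-varying VAR recursion at the analysis rate
(100 Hz):

* **Oscillators.**  Channels carrying a rhythm get AR(2) resonator
  blocks on the diagonal.  Default pole radius is 0.85, giving a few-Hz
  bandwidth comparable to scalp EEG rhythms.  The innovation variance is
  solved from the stationary AR(2) variance so a configured amplitude
  *A* (µV) yields RMS *A*/√2.  Defaults: theta 6 Hz / 7.5 µV on the
  centro-parietal set, alpha 10 Hz / 10 µV on the parieto-occipital set
  (the amplitude scale follows the grand-mean band amplitudes the
  experiment reports, ~7.5–10 µV).
* **Planted couplings** are band-limited AR cross-terms: a short FIR
  bandpass kernel (5 taps, peak in-band gain = the configured coupling
  gain) placed at the configured lag in the source→target block, its
  gain stepping from the pre-onset to the post-onset value at the onset
  (a ramp is available).  Because the coupling lives in the AR
  coefficients, gPDC has a true nonzero target and direction.  The
  companion-matrix spectral radius of the pre- and post-onset systems is
  checked (< 1) before simulation; an unstable configuration is rejected
  with the offending regime named.
* **Sensor-level components** are synthesized at the acquisition rate
  (1000 Hz) after polyphase-upsampling the neural trace: white sensor
  noise (4 µV at 1000 Hz ≈ 1.6 µV after decimation), the sway-related
  interference (2.6 Hz plus harmonics at amplitude/k, phase-locked to
  the onset across trials when flagged), an impulse-like biphasic onset
  artifact, and stereotyped ocular blinks (Poisson arrivals, biphasic
  300 ms pulses) propagated into the scalp channels with fixed
  coefficients.  A post-onset alpha drop scales the alpha-band
  innovation by the configured depth for its configured duration.
* The platform-motion simulator produces a quiescent baseline and a
  sustained 2.6 Hz oscillation whose envelope rises within ~50 ms of
  anchor release, so a 5-SD threshold detector triggers essentially at
  the release sample.

What the generator does **not** emulate: volume conduction and field
spread from a head model, 1/f background with realistic spatial
correlation, non-stationary artifact families (muscle, electrode
drift), or behavioural variability in onset response latency.  Passing
tests therefore demonstrate correctness and calibration of the
estimators under a controlled AR ground truth, not performance on real
EEG.

### Choice of oscillator bandwidth and noise level

Both were frozen while designing the generator against null (no
coupling) simulations.  A near-unit pole radius (0.97) makes the
channel's AR polynomial nearly singular at the rhythm frequency; after
gPDC's column normalization, estimation noise in that column then
saturates toward 1/√D regardless of the estimator — a property of pure
AR(2) resonators that real EEG, whose rhythms ride on comparable
broadband background, does not share.  The 0.85 radius and the ~1.6 µV
effective sensor noise keep the fitted polynomial well conditioned
across 0–30 Hz, which is the regime in which the study's discretization
thresholds (0.08/0.10/0.12) are meaningful.

## Preprocessing

* **Onset detection**: first sample whose displacement deviates from
  the mean of the preceding 5 s baseline by more than 5 baseline SDs on
  either motion axis (running baseline statistics).
* **Epoching**: 8 s epochs, 3 s pre-onset + 5 s post-onset; trials with
  insufficient margin are dropped with a warning and the cohort is kept
  rectangular at the minimum per-subject trial count.
* **Common average reference** over EEG channels (EOG excluded),
  exactly zero-mean per sample.
* **Ocular correction** (regression family): one propagation
  coefficient per channel, estimated on event-related-average-subtracted
  EEG vs EOG pooled over all trials, then raw scaled EOG subtracted.
  Order of operations defaults to re-reference → ocular-correct and is
  switchable.
* **Decimation**: order-8 Chebyshev-I low-pass (0.05 dB ripple, cutoff
  0.8·(fs/2)/factor — the classic `decimate` convention) applied
  zero-phase, then every factor-th sample kept.  Zero-phase filtering is
  chosen deliberately: a causal pass would delay the onset.  Note the
  even-order Chebyshev-I ripple puts DC down 0.05 dB (twice, with
  forward–backward filtering); tests account for this.

After 1000→100 Hz decimation the Nyquist frequency (50 Hz) is 8.33× the
theta peak and 5× the alpha peak.

## Multi-trial Kalman tvMVAR

State-space: the vectorized AR(p) coefficients follow a random walk;
with diagonal measurement noise the pD²-dimensional problem factorizes
into D independent filters of dimension pD (one per target channel,
shared regressor z(t) = stacked p previous samples of all channels):

    a_i(t) = a_i(t−1) + w(t),   w ~ N(0, c2²·I)
    x_i(t) = z(t)ᵀ a_i(t) + e_i(t),   Var e_i = r_i(t)

`c2 = 0.005` is the random-walk **step width** — a standard deviation,
so the process variance is c2² = 2.5·10⁻⁵.  We fixed this reading after
checking both: with variance c2 the estimator's gPDC null floor is
0.2–0.3, far above the 0.08 lower discretization bound that the study
calibrated to sit just above its stable-surface baseline; with variance
c2² the cohort-scale floor lands at ~0.05, consistent with that
calibration, while a planted step change in a coefficient is still
tracked within 1 s at 100 Hz.

`c1 = 0.02` adapts the measurement-noise variance by exponential
smoothing of the squared innovations, r ← (1−c1)·r + c1·ν², initialized
at the per-channel data variance.  Multiple trials update the same
state sequentially at each time step before the filter advances
(trial-sequential fusion); a trial-averaged innovation variant would be
a one-line change and is noted as the main alternative reading of the
multi-trial scheme.

The first 1 s of each coefficient trajectory is a convergence burn-in:
diagnostics and the condition-wise node-strength averages exclude it.
Model order defaults to p=20 at 100 Hz (the study's operating point,
selected by AIC and fixed); a pooled-OLS AIC table over candidate
orders is provided (`select_order`), with all candidates conditioned on
the same samples so their likelihoods are comparable.  Reduced-scale
tests use p=8, which covers the planted coupling kernel (lag 2 + 5
taps).

From the fitted trajectory, Ā(f,t) = I − Σ_k A_k(t)·e^(−i2πfk/fs) gives
the parametric amplitude map √diag(H Σ H*) with H = Ā⁻¹ (unnormalized
spectral amplitude; only peak locations are interpreted) and the gPDC

    π(i←j,t,f) = (|Ā_ij|/σ_i) / sqrt(Σ_m |Ā_mj|²/σ_m²),

column-normalized (Σ_i π² = 1 per source) and in [0,1].  The direction
convention π(i←j) = influence of source j on target i is used
everywhere, including exports.

### Group-level (grand-mean) networks

Group networks are computed from the **parameter-averaged** grand model:
AR coefficient trajectories (and residual variances) are averaged across
subjects before the gPDC transform.  Averaging in the coefficient
domain suppresses estimation noise by √n_subjects; averaging the
magnitude-valued PDC maps instead would retain the folded-noise bias of
each subject's estimate.  Tensor-level averaging remains trivially
available (`np.mean` over `PDCTensor.values`) and is what the 4-mode
tensor decomposition implicitly operates on, since it receives the
per-subject maps unchanged.

### Known limitation: common-average reference and identifiability

CAR makes the EEG channels sum exactly to zero, so the regressor space
loses one dimension and the common-mode coefficient direction is
unidentified; under the random-walk prior it drifts, inflating the gPDC
noise floor by an amount that grows as the montage shrinks (measured:
+0.18 at D=11 and desk-scale cohorts).  With 32 channels and a
37-subject grand mean the effect is minor, which is presumably why it
is invisible in the original analysis.  The pipeline keeps CAR (it is
part of the study's preprocessing); the desk-scale calibration tests
run the decimation-only chain so that they measure estimator
properties, not montage-size artifacts.

## Time–frequency analysis and artifact screening

The matched Gabor transform is realized as a multi-window Gabor filter
bank (Gaussian windows, default widths 0.25/0.5/1.0 s) with per-tile
matched-window selection by maximal amplitude; amplitudes are calibrated
so a unit sinusoid reads 1 (±2%).  The full matching-pursuit iteration
of the original MGT is intentionally out of scope; this surrogate keeps
its two used properties — per-component time–frequency adaptivity and
phase extraction.

The phase-locking index across trials, PLI(t,f) = |mean_trials e^{iφ}|,
is thresholded by the large-sample Rayleigh critical value
R_crit = √(−ln α / n); with the hundreds of trial instances involved the
finite-n correction is negligible.  The binary PLI maps are screened for
the sway interference: each harmonic k·f0 (default f0 = 2.6 Hz, k ≤ 4)
is scored by the persistence (time fraction ≥ 0.5 in the 3.5–8 s
window) of its most persistent frequency bin within a ±0.5 Hz guard
window; an analysis band is declared contaminated when a flagged
harmonic lies within the guard band of the band's edges.  By this rule
a phase-locked component at 5.2 Hz (the second harmonic) contaminates
the 5–7 Hz theta band — it lies inside it.

## Networks and statistics

ROI means (frequency band × time interval boxes, default theta 5–7 Hz
and alpha 9–11 Hz × TI1..TI4 = 3.5–4.5 … 6.5–7.5 s, excluding the
onset-artifact window 3–3.5 s) are discretized at 0.08/0.10/0.12 with
half-open bins assigned upward; boundary 0.12 → level 3.  Node strength
is the sum of in- and out-weights; ANS is its mean over nodes, computed
on undiscretized values.  Condition-wise ANS time-averages the tensor
within BSS (burn-in excluded) and BUS separately, per frequency bin.

The bootstrap confidence tube resamples **subjects** with replacement
(1000 replicates), takes the across-subject mean time course per
replicate, and uses the pointwise 2.5%/97.5% quantiles.  Pointwise (not
simultaneous) bounds are an interpretive choice, as is subject-level
resampling.  At n=37 the percentile tube empirically covers the true
mean at ≈ 93–94% rather than the nominal 95% — the familiar small-n
undercoverage of the percentile bootstrap; the acceptance calibration
reports the measured value.  Condition differences in ANS are tested by
two-sided paired t-tests per frequency bin with Bonferroni correction
over the analyzed bins.

## 4-mode PARAFAC

The per-subject gPDC maps of all directed pairs form a tensor
(pairs × time × frequency × subject); pair order is source-major over
the alphabetically sorted electrode subset (self-pairs skipped) and is
recorded in the tensor metadata.  The decomposition minimizes the
Frobenius reconstruction error under a nonnegativity constraint on all
modes, using hierarchical alternating least squares (HALS) column
updates — monotone in the reconstruction error — with multiple random
restarts (best fit kept), convergence at relative fit change < 1e-8 or
500 iterations, and full determinism given the seed.  Nonnegativity is
an assumption, not something the source analysis states: PDC values are
nonnegative and the factor loadings are read as strengths; plain ALS is
available via `nonnegative=False`.  Scale indeterminacy is resolved by
unit-normalizing all modes except the first (space), which carries the
factor scale.  The factor count M is user-set (M=5 in the source
analysis); the core-consistency diagnostic is reported but not used for
automatic selection — note that for strongly correlated nonnegative
factors it is routinely large and negative.  Factor similarity is the
product over modes of Tucker's congruence coefficient, greedy-matched;
for M ≤ 5 the greedy matching agrees with exhaustive permutation search
in the tested settings.

## Problem sizes in the shipped tests

The test suite and the reproduction script run at desk scale, chosen as
the smallest sizes at which each property is identifiable: 5-channel
montage (Cz, CPz, O1, Oz, O2), 3 subjects × 10 trials and order p=8 for
the 50-seed recovery checks; a 37-subject cohort for the null-floor
network check; 40,000 null bins for the Rayleigh calibration; 1000
cohorts × 1000 replicates for the tube coverage; 15×12×10×8 planted
rank-3 tensors for the PARAFAC checks.  The full-scale configuration
(11 or 32 channels, 37 subjects, p=20) is the package default and runs
in minutes, not hours, but is not exercised per-test.
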