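# Methods

## The design being modeled

The pipeline targets the standard video-viewing psychophysiology design:
each participant provides a two-minute resting baseline and then watches a
sequence of short emotional videos (10.5–30.5 s), rating a set of appraisal
items on a 1–5 scale after each video (with an explicit "does not apply"
code). During the session three facial EMG sites (zygomaticus major,
corrugator supercilii, frontalis), electrodermal activity and a beat-to-beat
RR-interval series are recorded; EMG and EDA at 1000 Hz. The analysis
aggregates each video to one 134-dimensional feature vector and asks, per
appraisal item, how well the ratings can be predicted across subjects.

## Synthetic data generator

The generator emulates the *structure* of such a study, not its
physiological detail. Each (subject, video) pair carries five latent
properties — the burst amplitudes of the three EMG sites, the electrodermal
phasic event rate, and the RR variability — drawn log-normally around
per-subject effects, so latents vary both within and between subjects.

* **EMG**: band-limited Gaussian noise (60–250 Hz, surviving the filter
  chain) amplitude-modulated by a resting tone plus Hann-window activity
  bursts, scaled by the amplitude latent (0.05 mV per unit); additive
  low-frequency movement artifact (< 40 Hz, 0.05 mV), a 50 Hz line
  component (0.02 mV) and a per-subject DC offset. These artifacts are
  exactly what the preprocessing chain is designed to remove.
* **EDA**: a tonic level (5 µS) with slow drift plus phasic events at the
  latent rate, each a rise/decay difference-of-exponentials (0.7 s / 2 s).
* **RR**: one continuous Gaussian AR(1) series (lag coefficient 0.6) around
  the configured mean, whose innovation scale follows the piece of the
  session timeline the beat falls in (per-video latent variability during
  videos, a subject-level value elsewhere), reflected into the
  physiological range 300–2000 ms.
* **Ratings**: item score = 3 + 2·direction·strength·g(z) + N(0, noise_sd),
  where z is the standardized latent and g a monotone link (linear z/2,
  saturating tanh, or a hard threshold at the median), rounded half-up and
  clipped to {1..5}. Items without an effect specification are uniform
  noise; every entry is independently replaced by the missing code with the
  configured probability. Defaults follow the study conditions: 157
  subjects, 10 videos, 2-minute baselines, and a 14% missing rate (the
  average share of "does not apply" answers implied by the study's
  per-item sample sizes).

What the generator does **not** emulate: motor-unit physiology, EMG
crosstalk between neighboring facial sites, respiratory or circadian
structure in HRV, stimulus-locked response timing, or correlated latents
across channels. Passing recovery tests therefore demonstrates that the
pipeline's statistical machinery recovers structure that is present; it
does not validate the physiological realism of any feature on real data.

## Preprocessing

Filters are Butterworth (order 4 for high-/low-pass; the 50 Hz notch is a
second-order IIR design with a 0.5 Hz total stop-band width, i.e. quality
factor 100), applied forward–backward so features see no phase distortion
and segment alignment cannot drift. Whether the original protocol used
zero-phase filtering and which orders it used is not specified anywhere;
both are configurable and the defaults are recorded as assumptions in every
run manifest. Filtering is applied per video segment after segmentation;
edge transients are accepted because all features aggregate over ≥ 6 s. The
EMG baseline correction subtracts the mean of the *identically filtered*
resting baseline, keeping the correction on the scale of the corrected
signal. Segments are half-open [onset, offset) in seconds from stream
start; an RR interval belongs to the segment containing its terminating
beat.

## Features

All sampled-channel sums are expressed as per-sample means, per-transition
percentages, or spectral integrals, making every feature independent of
segment length for a stationary signal (verified by a 50-simulation
length-invariance test). Conventions worth noting:

* Trimming removes 20% of the sorted rectified samples from each tail; the
  TMAV smoother is a moving 20%-trimmed mean with a 100 ms window
  (configurable).
* The "absolute 3rd–5th moment" features are absolute temporal moments
  |mean(xᵏ)|; the 1st–3rd spectral moments are integrals ∫P(f)·fᵏ df of the
  one-sided periodogram of the demeaned segment. Median/mean frequencies
  are computed on both the amplitude (√P) and power (P) spectra.
* Thresholded features use 0.005 mV for the thresholded zero crossings and
  Wilson amplitude and 0.016 mV for the myopulse percentage — conventional
  surface-EMG values; the protocol states only the 0.005 mV zero-crossing
  threshold, so the other two are configurable assumptions.
* AR(1–4) coefficients come from the order-4 Yule–Walker equations
  (biased autocovariances, prediction form); a zero-variance series yields
  zero coefficients rather than an error.
* The log detector floors |x| at 1e-12 so all-zero segments stay finite.
* HRV: "RMSSD" is the root mean square of successive differences (the
  standard reading; a configuration switch computes RMS of the raw
  intervals instead). The LF/HF ratio integrates a Lomb–Scargle
  periodogram of the beat series over 0.04–0.15 / 0.15–0.40 Hz; on 10–30 s
  segments this quantity is physically unstable and the contract is only
  finiteness and non-negativity. Histograms for the triangular indices use
  the conventional 1/128 s (7.8125 ms) bins anchored at zero; the
  relative-RR histogram uses 1% bins; TINN is the base width of the
  least-squares triangle over the RR histogram with its apex fixed at the
  modal bin. A constant RR series returns SD2/SD1 = 0 via a 1e-9 ms floor
  on SD1. HRV features require at least 4 intervals, so recordings must
  span roughly ≥ 5 s at resting heart rate.

## Benchmark

Out-of-sample R² is computed per test fold against the *test-fold* mean and
aggregated as the unweighted mean over the 100 (20 repetitions × 5 folds)
scores. Subjects, not rows, are randomized: within each repetition subjects
are shuffled by a seeded permutation and dealt round-robin into five folds,
so no participant ever spans a train/test boundary (asserted on every
split). Zero-variance test folds — possible at very small synthetic n — are
skipped with a warning and the aggregate taken over the remaining folds.

Learner defaults: the featureless learner predicts the training mean (its
fold R² is ≤ 0 by construction, a useful sanity floor); ridge regression
uses penalty λ = 1 on standardized features, preceded by the fold-local
outlier step (values beyond 3 sample SDs of the training fold eliminated
and imputed by seeded draws from the column's retained training values,
thresholds learned on train and applied to both sides); the random forest
uses 500 trees, ⌊p/3⌋ candidate features per split, minimum node size 5 and
unlimited depth — the de-facto regression defaults. The ridge penalty and
the forest settings are assumptions (the original "default settings"
footnote is not specific) and are echoed in the run manifest.

## Blocked importance

R²_B trains the forest on one channel's columns alone; ΔR²_B is the
difference between the full model and the model without the channel, both
evaluated on the same subject-blocked 60/40 split with the same forest
seed (the shared-split contract, asserted in tests). Iteration i derives
its split from seed + i, so the two measures share splits when requested
with the same seed. Robustness again requires ≥ 85% strictly positive
iteration values, and reports flag (rather than drop) non-robust entries.

A finite-sample caveat, measured during development and visible in the
analysis scripts' output: when a channel's complement carries *no* signal,
the complement forest overfits noise and scores systematically negative
out-of-sample R² (≈ −0.1 at a few hundred rows, decaying only slowly with
n), so ΔR²_B then exceeds R²_B by roughly that margin. The effect is a
property of the estimator, not of the implementation — with realistic,
partially redundant channels the complement model is well-behaved, and a
fully duplicated channel's ΔR²_B is ≈ 0 as it should be.

## ALE interpretation

The interpretable candidate set is derived by rule: the amplitude family
(MAV, trimmed MAV, TMAV, square integral, RMS, absolute 3rd–5th moments,
log detector) on the four sampled channels plus the time-domain HRV
features (excluding the LF/HF ratio and the Poincaré shape measure).
Candidates are screened with the R²_B machinery on single features, with
tree depth capped at 3 to prevent overfitting; "most robust" means the
robustness gate first, then the highest mean, ties broken lexicographically
for determinism. First-order ALE uses quantile-based interval boundaries
restricted to the feature's 5–95% quantile range; per interval the mean
prediction difference between upper and lower boundary is accumulated and
the curve centered by the occupancy-weighted mean (the centering identity
holds to 1e-10). The default is 20 intervals; at desk scale (n ≈ 100–200
rows) tests and analysis scripts use 5 intervals so each interval holds
~20–30 rows and the accumulated forest steps are resolvable above
step-function noise.

## Problem sizes and determinism

All shipped tests and scripts run at desk scale as a deliberate design
choice: studies of 6–20 subjects × 3–8 videos of 5–9 s, forests of 25–200
trees, importance resampling of 30–100 iterations; the recovery fixture
uses ten independently seeded studies of 15 subjects × 6 videos. Every
random stream (generator, fold assignment, splits, forests, imputation)
derives from explicit integer seeds, so all artifacts are byte-reproducible
given the seed.

## Known limitations

Single-item 1–5 ratings cap attainable R² well below 1 even at zero latent
noise (discretization); the ridge learner is fragile at desk-scale n with
134 predictors (its aggregate can be strongly negative on noise items,
which the benchmark reports honestly); the LF/HF feature is noise on short
segments; and the generator's independence of latents across channels means
cross-channel shared variance — the interesting regime for ΔR²_B on real
data — is only exercised through explicit duplicated-block constructions in
the tests.
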