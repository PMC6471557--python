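# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and what the test suite does and does not establish.

## Synthetic oddball flight EEG

The generator emulates the statistical structure the analysis assumes,
with three independently seeded components per condition (events, ongoing
signal, artifacts — so disabling one does not shift another).

**Events.** Each session carries `n_stimuli` = 320 auditory stimuli split
evenly between the two load conditions; targets are an exact
`round(n·0.25)` per condition by shuffled assignment (80/240 per
session), not Bernoulli draws, so the split is reproducible. Inter-onset
intervals are uniform on `iti_mean ± iti_jitter` = 2000 ± 1000 ms; the
first stimulus follows the 30-s calibration lead-in.

**Ongoing signal.** Per channel:

- a 1/f background (PSD ∝ f⁻¹, spectrally shaped Gaussian noise) scaled
  to 10 µV RMS. Channels share a common source with weight √ρ
  (ρ = `spatial_correlation` = 0.95) plus an independent stream with
  weight √(1−ρ). The high correlation stands in for volume conduction;
  without it no leave-one-out channel-correlation criterion at 0.85 could
  ever retain clean data.
- amplitude-fixed sinusoids at band centres (δ 2.5, θ 6, α 10, low-β
  14 Hz) with a fresh uniform phase per 1-s block, shared across channels
  (one source seen by all electrodes). Default amplitudes are 2/1.5/2/1 µV
  (δ/θ/α/β) everywhere, except the load contrast: α at Pz 5 µV (low) vs
  2 µV (high) and θ at Oz 3.5 vs 1.5 µV. These contrasts were fixed once,
  during design, at a level that makes the configured effect clearly
  recoverable by the continuous pipeline (≈96% balanced accuracy averaged
  over seeds in pilot runs); they model the reported direction of the
  load effect (parieto-occipital α and θ stronger while monitoring than
  while flying), not its real-data magnitude.

**Evoked response.** A Gaussian-windowed positivity (peak `p300_latency`
0.45 s — inside the 350–600 ms analysis window — SD 0.06 s, support
truncated at ±3 SD) is added at each target onset with a parietal-dominant
topography (Pz 1.0, P3/P4 0.9, Oz 0.8, Cz 0.5, Fz 0.3) and peak amplitude
8 µV under low and 4 µV under high load. With the 10 µV background this
gives single-trial ERP SNR < 1.

**Artifacts** (ground truth for the cleaning stage, logged with onset,
duration, kind, channels, amplitude; never inside the calibration
lead-in):

- *Blinks* (8/min): biphasic low-frequency pulses, frontal-dominant
  (Fz ≫ Pz), 150 µV peak at Fz.
- *Motion bursts* (1/min, 0.5 s, 500 µV peak): one broadband (< ~28 Hz
  dominant) waveform projected onto ≥3 channels with per-channel gains of
  balanced random polarity — i.e. a rank-1 artifact subspace, as cable and
  electrode motion produces, and spatially distinct from the common
  background mode. Bursts have a refractory separation (≥ 1 s) so two
  never superimpose into a rank-2 event.

**What the generator does not model:** realistic head-model forward
projection, inter-subject variability of effect sizes and topographies,
non-stationary drifts of electrode impedance, acoustic properties of the
stimuli, line noise. Passing tests therefore demonstrate correctness of
the *pipeline*, and recoverability of *configured* effects — they do not
predict real-flight accuracies, where the same pipeline is reported far
lower.

## Preprocessing

All filters are even-order (default 250 → 251 taps) Hamming-windowed
sincs: integral group delay of 125 samples, compensated exactly in a
single pass with reflection padding, so output length equals input length
and a steady-state sinusoid exits with zero lag. High-pass kernels are
built as δ − (DC-normalized low-pass), giving an exact DC null; band-pass
kernels have unity gain at the band centre. The epoch grid is half-open
[tmin, tmax): −0.2 to +1.0 s at 500 Hz is exactly 600 samples, 0–0.6 s at
50 Hz exactly 30. Downsampling is pure keep-first decimation, relying on
the mandated 1–15 Hz pre-filter rather than an extra anti-alias stage.
Boundary events whose epoch would leave the recording are dropped and
counted, never fatal. Both pipelines filter the continuous data 0.5–30 Hz
before epoching and cleaning; this mirrors the stated processing order
and keeps sub-band drift out of the ASR calibration statistics.

## Artifact subspace reconstruction

Calibration on the 30-s clean segment: covariance of 0.5-s windows at 50%
overlap, combined arithmetically (*classic*) or by the Riemannian
geometric mean (*riemannian*, fixed-point iteration warm-started at the
arithmetic mean, tolerance 1e-6, ≤ 50 iterations). The mixing matrix is
the principal square root M = C^½; per principal component the threshold
is μ + k·σ of windowed component RMS, with the burst criterion k = 70 —
the lenient value appropriate for noisy in-flight data (ordinary lab use
would pick 5–20). The moment estimator (μ, σ) is used instead of a
truncated-Gaussian fit; at k = 70 the two are operationally
indistinguishable on clean calibration data, and k is exposed.

Processing slides 0.5-s windows at 75% overlap; per window the covariance
is eigendecomposed and a direction u is rejected when its variance
exceeds Σᵢ tᵢ²(Vᵀu)ᵢ²; rejected directions are reconstructed from the
kept subspace through M (clean-subspace remixing), and windows are
blended with raised-cosine overlap-add, so unflagged data passes through
bit-identically. Detections are dilated by one hop with a 0.25-relaxed
bound: windows straddling an artifact edge hold too little energy to
cross the lenient threshold on their own, yet their overlap-add share
would otherwise reinstate part of the artifact; the relaxed bound still
sits about two orders of magnitude above clean-background eigenvalues, so
behavior on clean data is unchanged. The stimulus-locked pipelines apply
the same machinery per epoch, always with the single model calibrated on
the first 30 s.

Accompanying continuous-data criteria: flatline channels (constant run
≥ 5 s) are removed; per 1-s window a channel is flagged when its
correlation with a least-squares prediction from the other five channels
(< 45 Hz content) falls below 0.85 — with six channels, leave-one-out
regression replaces RANSAC subsampling — or when its high-band (> 45 Hz)
to low-band RMS ratio is a robust-z outlier (> 4, median/MAD over
windows); a window is dropped when more than 10% of channels are flagged.

## Features and classification

Band power features use the cached-covariance identity: the mean squared
output of a spatial filter w over a window equals wᵀCw for the window's
(uncentered) sample covariance C, so per-fold CSP refits and permutation
nulls reuse per-epoch band covariances instead of re-filtering. CSP class
covariances are means of per-epoch Ledoit–Wolf-shrunk covariances
(analytic λ, clipped to [0,1]; a zero-variance matrix forces λ = 1);
filters are the n_pairs extreme generalized eigenvectors, ordered
extremes-first and normalized to wᵀ(Σ_A+Σ_B)w = 1. The log is natural.
"Two pairs" of CSP filters means 4 filters per band, forced by the
4 × 4 = 16 feature arithmetic.

sLDA uses the pooled within-class scatter with the same analytic
shrinkage, equal priors (the classified conditions are balanced by
design; the oddball 25/75 imbalance concerns stimuli, not classes), and a
midpoint bias. Sensitivity is defined on the high-load class. mRMR
discretizes features into 8 equal-frequency bins and greedily maximizes
I(f;y) − mean I(f;s) over selected s (the MI-difference variant), ties to
the lowest index. Cross-validation shuffles once with the run seed, then
assigns round-robin per class (stratified within ±1 epoch); CSP, mRMR and
all shrinkage are fitted inside each training fold only, and the fused
pipeline selects its top 20 per training fold.

## Interpretation and group statistics

Activation patterns follow the forward-model identity a = Σ·w, with Σ the
training-fold feature covariance (LDA level) or the training composite
Σ_A+Σ_B (CSP level); no normalization, since only the rank order of |a|
is consumed. The tally takes, per fold, the band/filter of the largest
|LDA pattern| entry among band-power features and then that filter's
dominant channel; ties break to the lowest index.

The group contrast is a paired sign-flip bootstrap: observed statistic =
mean per-subject difference; null = random sign flips of each subject's
difference; two-sided p = (1 + #{|null| ≥ |obs|})/(n_boot + 1) — valid
(conservative) by construction, default 10,000 resamples at α = 0.01,
pointwise with no cluster correction. Note that the sign-flip null scales
with √(E[D²]/n), which under a true shift includes the shift itself:
exact power for a 1-SD shift at n = 18 and α = 0.01 is ≈ 0.78, lower than
the t-test intuition suggests; the simulated full-scale P300 contrast
(≈1.6 SD) is detected in > 99% of cohorts.

Morlet band power (group-level spectra) uses 7-cycle complex Morlet
wavelets on a 1-Hz scale grid; band power integrates (sums) the
time-averaged squared magnitude over in-band scales, so a flat spectrum
yields power proportional to bandwidth. Seven cycles (rather than a more
common five or six) keeps a pure tone's leakage into the neighboring band
below 10%.

## Problem sizes used in the test suite

Module tests run the generator at 120–250 s per condition with 40–80
stimuli; the acceptance suite runs the continuous pipeline and the
permutation null at the full 500-s/320-stimulus defaults, burst
suppression over 20 generator seeds at 120 s, bootstrap calibration over
500 null simulations, and the cohort power check over 10 cohorts × 18
subjects at full session length. These sizes are the package's choice of
desk-scale reproduction; all stage parameters are the study defaults
throughout.

## Known limitations

- EDF I/O is a minimal 16-bit implementation (one 1-s record per second,
  µV only); BrainVision/XDF and streaming input are out of scope.
- ASR is offline and block-based; no streaming state, no automatic cutoff
  selection, no model adaptation across epochs.
- The classifier chain is deliberately linear (CSP + sLDA); no
  hyperparameter search, nonlinear models, or cross-subject transfer.
- Repeated-measures ANOVA is not provided; the bootstrap contrast is the
  supported group-level inference.
- Real-data accuracy levels are not reproducible here: the flight EEG was
  never deposited, and the generator makes no attempt to calibrate its
  noise to that environment.
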