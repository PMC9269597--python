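# Methods

## Problem and pipeline model

`facehrv` treats contactless HRV measurement as a two-branch estimation
problem. Both branches end in the same representation — a train of systolic
peak times, differenced into NN intervals (ms) — and everything downstream
(the feature catalog, the agreement statistics) is branch-agnostic.

The video branch assumes that the spatial mean of the red channel over a
stable facial region carries a pulse-synchronous component that is small
relative to sensor noise and illumination, but band-limited to the heart
band. Three design consequences follow:

* the ROI must be *stable*: detector jitter of a few pixels changes the skin
  mix inside the box and injects broadband noise, so the committed box moves
  only when the raw detection translates ≥ a threshold (default 10 px at
  720p, scaled with frame height). Missing detections carry the last box
  forward; leading misses borrow the first hit. Box size is frozen to the
  first committed box so every cropped frame has one shape.
* color magnification is *linear*: the clip is Gaussian-pyramid downsampled
  `level` times (blur σ = 1, reflective boundary, decimation by 2), each
  coarse pixel is temporally filtered with an ideal FFT band-pass
  (coefficients outside [f_lo, f_hi] zeroed, DC removed), scaled by
  α · channel_gains, bilinearly resized back to the input shape, and added
  on. For spatially uniform input the chain reduces to `(1 + α)` gain on
  in-band temporal components, which the tests exploit as a closed form.
  Defaults: level 4, α 50, band 0.67–3.0 Hz (40–180 bpm), equal channel
  gains. Processing stays in RGB because only the red channel is consumed
  afterwards.
* peak detection operates on a *preprocessed* signal: linear detrend, then a
  zero-phase 3rd-order Butterworth band-pass over the same heart band, so
  the peak height rule can be expressed as a threshold μ + kσ with μ ≈ 0.
  Defaults: k = 0.5, minimum spacing 0.33 s (180 bpm ceiling). The signal is
  reflected at its ends before peak picking so a systolic bump truncated by
  the recording boundary still presents a local maximum; boundary bumps
  suppressed by the band-pass itself are nevertheless undetectable, which is
  why round-trip tests evaluate the interior of the recording (0.5 s
  margin).

NN intervals outside 300–2000 ms (30–200 bpm) are treated as ectopic beats
or detection artifacts and dropped together with their boundary rather than
merged; after filtering, `nni` and `nni_times` (interval end times) remain
paired even though the cumulative-sum identity with `beat_times` then holds
only piecewise.

Two heart-rate definitions coexist deliberately: the count-based rate
60 · n_peaks / duration (`mean_heart_rate`, used for the between-branch
error metrics and the per-minute stratification) and the HRV feature
`hr_mean` = mean(60000 / nni). They differ under rate modulation and are
never interchanged.

## Feature catalog

63 features: 15 time-domain, 12 per spectral estimator × 3 estimators, 12
non-linear. Dispersion statistics (SDNN, SDSD, SD of differences, Poincaré
variances) use the sample convention (ddof = 1). nn20/nn50 count successive
differences *strictly* greater than the threshold. The time-domain names are
fixed: nni_count, nni_mean, nni_min, nni_max, nni_diff_mean (mean absolute
successive difference), hr_mean, hr_min, hr_max, sdnn, rmssd, sdsd, nn20,
pnn20, nn50, pnn50.

Spectral estimation: the tachogram (interval value vs. interval end time) is
cubically resampled at 4 Hz for the evenly-sampled estimators. Welch uses
256-sample (64 s) Hann segments, 50 % overlap, zero-padded to 4096 bins;
the autoregressive route is a Burg model of order 16 evaluated as a
one-sided all-pole spectrum; Lomb–Scargle runs directly on the uneven
(beat time, interval) pairs and is rescaled so its trapezoidal integral
equals the interval variance, giving all three estimators commensurate
ms²/Hz units. Per band (VLF < 0.04, LF 0.04–0.15, HF 0.15–0.4 Hz; the HF
top edge closed) the catalog reports the peak frequency, absolute
(trapezoid-integrated) power, relative power (normalized over the three
bands, summing to 1) and log power. A band not covered by the grid yields
explicit missing values, never silent zeros.

Non-linear catalog: SD1 = √(var(Δ)/2), SD2 = √(2·var(nni) − var(Δ)/2),
SD1/SD2, ellipse area π·SD1·SD2, CSI = SD2/SD1, CVI = log10(16·SD1·SD2),
SD2/SD1 (kept as its own catalog entry), the lag-1 autocorrelation of the
intervals, sample entropy SampEn(m = 2, r = 0.2·SD, Chebyshev distance,
strict inequality, self-matches excluded, both template counts over the
same n − m index range), and DFA α₁ (4–16 beats), α₂ (16–64 beats) and an
overall slope (4–64), each fitted over ~10 log-spaced window sizes with
per-window linear detrending. Any feature that cannot be computed is
reported as explicitly missing (`None`).

## Agreement analysis

Recordings that did not start/stop together are aligned by trimming the
longer member symmetrically (odd surplus: the extra sample comes off the
end); pairs overlapping < 60 s are rejected. Error metrics on the aligned
count-based heart rates: Me (signed mean difference), MAE, SD of
differences (sample), RMSE; RMSE ≥ |Me| and RMSE² = Me² + SD²·(n−1)/n hold
by construction. Because the referent of a printed "SD" column can be
ambiguous, the report also carries the SD of each branch's heart rates
separately. Per-minute stratification counts peaks in [60k, 60(k+1))
windows aligned to the trimmed common start; the trailing partial window is
discarded.

Feature agreement uses three tests per feature — Pearson product-moment,
Spearman rank, Kendall tau-b (tie-corrected) — each with its two-sided
p-value, computed over complete pairs (≥ 4 required; zero variance ⇒
missing). Benjamini–Hochberg is applied within each test's family (the
feature catalog, m = 63), and a feature is declared significantly
correlated only when q < 0.5 under all three tests. The 0.5 default is
unusually permissive for an FDR threshold; it is config-exposed and no
judgment is attached to it. The BH implementation is the package's own (the
step-up recursion is part of the specified surface) and is cross-checked in
tests against statsmodels and a brute-force recursion.

## Synthetic data: what it emulates and what it does not

The generator provides the statistical structure the pipeline assumes, not
photorealism:

* **RR series** — integral pulse frequency modulation: the instantaneous
  rate r(t) = r₀(1 + a_LF sin 2πf_LF t + a_HF sin 2πf_HF t) is integrated
  and a beat fires at every integer crossing (t = 0 is the integrator's
  reset beat), so the interval spectrum inherits controllable LF/HF power.
  Per-interval Gaussian jitter (default 3 ms in the benchmarks) adds the
  broadband floor real tachograms have; intervals are clamped to
  300–2000 ms and beat times rebuilt cumulatively so the interval/beat-time
  identity is exact. Default modulation amplitudes (3 % LF at 0.1 Hz,
  2.5 % HF at 0.25 Hz) are chosen for testability — they produce clearly
  measurable band powers at 10-minute durations — not to mimic any
  particular population.
* **PPG** — one unit Gaussian bump (σ = 50 ms) per beat plus white noise;
  this matches the low-complexity Gaussian-shaped waveform the peak
  detector's height rule assumes. Real PPG morphology (dicrotic notch,
  baseline wander, motion artifacts) is absent, so detector performance on
  this substrate bounds clean-signal behavior only.
* **Video** — static mid-gray background, uniform skin-tone patch, red
  channel inside the patch modulated multiplicatively by the (wider,
  σ = 120 ms) pulse waveform, i.i.d. Gaussian pixel noise. Frames are
  float32 in [0, 1] by default so 1 % modulations stay representable; an
  8-bit quantization flag emulates camera output when wanted. No face
  rendering, head motion, or illumination change is simulated — the
  face-detection stage is therefore exercised on a bundled photographic
  fixture, and synthetic tests drive the pipeline with a fixed ROI.

Consequently, passing tests demonstrate the algorithmic chain (magnification
gain, band selectivity, beat recovery, feature correctness, statistics) —
they do not certify performance on real faces, skin tones, lighting or
motion.

## Benchmark problem sizes

The end-to-end benchmarks use 10 paired 10-minute studies at 64×64 px /
30 fps (video) + 100 Hz (PPG) for the heart-rate agreement, and 45
10-minute PPG traces for detector precision, with mean rates spread evenly
over 55–90 bpm and per-study seeds derived from the base seed. 64×64 frames
with a 32×32 skin ROI retain the full temporal structure the method
operates on while keeping the video stack in memory; spatial resolution
only dilutes the ROI-mean noise, for which the noise level (1 % per pixel)
is already conservative relative to the 1 % modulation depth.

## Numerical choices and degenerate inputs

* Ideal temporal band-pass keeps bins with f_lo ≤ f ≤ f_hi inclusive; DC is
  always removed (f_lo > 0 in all presets).
* Pyramid upsampling uses order-1 (bilinear) zoom to the exact target shape
  (grid-aligned), so spatially constant fields are reproduced exactly and
  the α = 0 path is the identity.
* Burg on a pure line spectrum (zero jitter) is a known degenerate case for
  relative band powers; benchmark conditions include jitter, which real
  tachograms always have.
* Constant series: SDNN/RMSSD are 0; SampEn and the Poincaré ratios are
  explicitly missing; peak detection returns an empty train (σ = 0 makes
  the height threshold equal the constant — no strict local maxima exist).
* Ties in peak conflicts resolve toward the higher peak (scipy's
  `find_peaks` distance rule); detection ties in face boxes resolve toward
  the largest area.
* With fewer than 4 tachogram points, cubic resampling falls back to linear
  with a warning rather than failing.

## Known limitations

* The cascade detector is exercised on one bundled photograph; multi-face
  scenes, pose changes and illumination robustness are out of scope.
* The magnification stage implements a single amplification factor per
  chosen pyramid level, not a wavelength-dependent attenuation schedule,
  and no motion (phase-based) magnification.
* AVI input requires an imageio backend able to decode it; the lossless
  tested paths are PNG directories and `.npy` stacks.
* All filtering is offline (whole-clip FFT, zero-phase IIR); there is no
  streaming mode.
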