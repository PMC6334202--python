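# Methods

This note documents the models, parameter choices and numerical decisions
behind `afdfmap`, and what the synthetic validation does and does not show
about real recordings.

## Signal model and analysis chain

The pipeline assumes two simultaneously acquired multichannel recordings:
an atrial set (virtual electrograms estimated on the endocardium, or any
stand-in for them) and a torso set (dense body-surface electrodes), each
with a shared reference ECG lead. Fibrillatory atrial activity is treated
as locally quasi-periodic: each site oscillates near a fibrillatory rate in
4–10 Hz with decaying harmonics, superimposed with ventricular far-field,
mains interference and broadband noise.

The chain is: resample to a common rate → zero-phase band-pass → mains
channel QC → reference-lead alignment → QRS-T cancellation → windowed
spectra → DF/OI/F-ratio per channel-window → HDF mapping and the paired
torso-minus-atrial difference analysis.

### Preprocessing

* **Resampling** (default target 512 Hz) uses polyphase rational
  resampling (`scipy.signal.resample_poly`) with the rate ratio
  approximated as a fraction (denominator ≤ 10⁵, exact for the relevant
  1200, 2034.5 and 2048 Hz acquisition rates); the output is trimmed or
  zero-padded to `round(n·target/fs)` samples. Tones in the 4–10 Hz
  analysis band are preserved exactly to the grid resolution.
* **Band-pass** (default 2–50 Hz) is a moving-average cascade: a
  forward-backward moving-average low-pass of window `round(fs/high)`
  (10 samples at 512 Hz) minus a forward-backward moving-average baseline
  of window `round(fs/low)` (256 samples) applied to the low-passed
  signal. The forward-backward pass makes the filter exactly zero-phase —
  windows stay aligned across the two streams — and squares the magnitude
  response. Measured response at 512 Hz: DC is removed exactly, a 6 Hz
  tone loses < 0.5 dB, and everything at or above 100 Hz sits below
  −20 dB (−34 dB at the worst sidelobe near 128 Hz). The measured −3 dB
  points are approximately 1.2 and 16 Hz: the upper edge is soft, as
  inherent to moving-average filters — flat across the 4–10 Hz DF band but
  attenuating the upper OI harmonic windows by a few dB (≈ −4.6 dB at
  20 Hz). This depresses absolute OI values slightly; it does so
  identically for both streams and cancels in every paired comparison.
* **Mains QC**: a channel is invalidated when the full-record periodogram
  power summed over 50 ± 0.5 Hz exceeds 0.5% of total power. The ±0.5 Hz
  band (rather than one zero-padded bin) makes the criterion robust to
  spectral leakage.
* **Alignment** maximizes the normalized cross-correlation of the shared
  reference lead; a peak below 0.5 raises an error rather than silently
  mis-pairing windows. This replaces manual R-peak-based alignment with
  its deterministic equivalent.

### QRS-T cancellation

R peaks are detected on the reference lead (8–30 Hz zero-phase band
emphasis, squared envelope, adaptive threshold at 25% of the envelope's
99th percentile, 200 ms refractory, ±25 ms refinement on the rectified raw
signal). Per channel, the mean beat over a 100 ms pre / 450 ms post window
around each R peak is subtracted at every beat, with 20 ms raised-cosine
edge tapers so subtraction introduces no steps (steps would add broadband
power and bias OI downward). One global template per channel is used; with
fewer than 3 usable beats the signal passes through unchanged with a
warning. Averaging cancels the beat-locked ventricular component while the
atrial component — uncorrelated with beat timing when the heart rate
jitters — survives; on synthetic tone + beat-train mixtures the cancelled
signal correlates > 0.95 with the pure atrial component.

### Spectra and metrics

Each 4 s window (50% overlap between windows) gets its own spectrum,
zero-padded to `fs / 0.05` points so the grid spacing is exactly 0.05 Hz.
The `welch` estimator averages three Hamming-tapered 2 s sub-segments at
50% overlap inside the window; `fft` uses a single Hamming periodogram.
Both are exposed because the windowing question — Welch within the window
versus one periodogram — materially affects peak stability, and the Welch
variant is the default for its lower variance.

* **DF**: arg-max of power in the closed 4–10 Hz band; ties break to the
  lower frequency for determinism.
* **OI**: numerator windows are ±0.375 Hz around the DF and around each
  integer harmonic n·DF (n ≥ 2) while n·DF + 0.375 ≤ 20 Hz; the
  denominator is 0–20 Hz. Bins are included when they fall inside a window
  up to a 10⁻⁶-bin tolerance, and overlapping windows count each bin once,
  so OI ≤ 1 holds structurally. Harmonic windows sit at exact integer
  multiples by default; an option re-centers each on the local maximum
  within ±k. Note the denominator starts at 0 Hz even though acquisition
  high-pass filters leave little power below 1–2 Hz; this is deliberate so
  OI values are comparable with the convention used in the DF literature.
* **F-ratio test**: peak power over the mean of 10 neighbors per side.
  Zero-padded 0.05 Hz bins are strongly correlated, which would break the
  independence assumption behind the F(2, 2(F−1)) reference distribution,
  so neighbors are sampled at the native pre-padding resolution (0.5 Hz
  for the Welch estimator, 0.25 Hz for FFT) while the peak remains the
  padded-grid peak; contiguous padded bins are available as an option.
  The critical value is computed from the F distribution (3.23 for the
  default 21 frequencies) rather than hard-coded, so changing
  `n_neighbors` keeps the test calibrated. Neighbors falling off the grid
  are truncated with a warning.
* **Harmonic classification** (only for non-significant peaks): the
  strongest frequency g in [1 Hz, DF) and in [4 Hz, DF) is found; the peak
  is labelled a harmonic of g when it lies within ±k of an integer
  multiple of g and g carries at least as much power. The [4, DF) search
  (slower fibrillatory driver) takes precedence over [1, DF) (cardiac
  cycle rate). The power-ordering requirement is this package's choice of
  a minimal, deterministic criterion; no community-standard rule exists.

### HDF mapping and paired analysis

Per window and dataset, channels are eligible when OI strictly exceeds the
threshold; the HDF is the maximum DF among eligible channels and the
hosting area is every eligible channel with DF ≥ HDF − 0.25 Hz. Windows
where the HDF-attaining channel is harmonic-flagged on either dataset are
excluded from the paired analysis. The OI-threshold sweep (grid 0–1, step
0.1) reports the percentage of windows with a defined HDF under two
denominators — all windows, and windows surviving harmonic exclusion —
because both framings are useful and they differ; hosting-set changes at a
chosen threshold (default 0.5) versus threshold 0 are summarized as
persisting = 100·|before ∩ after|/|before| and
new = 100·|after \ before|/|after|, with per-window medians and IQRs.

Differences (BSM − VEGM HDF) are binned by VEGM HDF into half-open
[x.0, x.5) bins (centers x.25/x.75). The exponential trend is
d(f) = −a·exp(b·(f − f₀)) + c with f₀ fixed at the lowest bin center:
this captures a flat-then-accelerating negative difference with
interpretable parameters (c the small-driver offset, a·exp(b·Δf) the
damping growth). Initialization log-linearizes c₀ − d around a c₀ slightly
above the maximum median; Levenberg–Marquardt refinement runs with 5
seeded jittered restarts, keeping the lowest-SSE converged fit. CIs are
asymptotic t-intervals from the parameter covariance (coverage verified at
≥ 90% over 100 noisy replicates in the suite); constant medians return the
degenerate flat fit a = 0 rather than an error. Rank tests
(Mann-Whitney/Wilcoxon) are delegated to scipy.

## The synthetic generator

The generator emulates the features the analysis relies on, with exact
ground truth:

* **Sources**: each node emits Σₕ aₕ·cos(h·φ(t)) with harmonic amplitudes
  (1, 0.4, 0.15) — matching the DF + decaying-harmonics structure OI
  assumes — where dφ/dt tracks the node's frequency modulated by slow
  seeded jitter (default 1% SD, smoothed below ~1 Hz), emulating
  fibrillatory cycle-length variability. Driver nodes (default 5% of the
  atrium, the compact-fast-source regime) run at `driver_freq` (default
  9 Hz), the rest at `background_freq` (default 6 Hz). Initial phases form
  traveling waves radiating from a focus per region (0.5 rad of phase per
  radian of arc), so regional activity sums coherently under spatial
  mixing, as propagating activation does.
* **Geometry**: nodes on a unit-sphere cap of half-angle 135° (a closed
  chamber with an opening), electrodes on a concentric shell of radius 2.
  The 2:1 shell ratio gives nearest-to-farthest distance ratios of about
  3, enough spatial contrast that a large driver area can dominate nearby
  electrodes while a small one cannot — the regime of interest.
* **Lead field**: w(e,n) ∝ 1/d², neighborhood-smoothed (radius 0.3) and
  row-normalized; purely spatial, memoryless mixing. This isolates the
  claimed mechanism — frequency damping by spatial averaging — without
  conflating it with temporal filtering.
* **Ventricular far-field**: a stylized QRS-T waveform (Gaussian Q/R/S
  deflections and a broad T wave, 1 Hz mean rate, 5% RR jitter) scaled
  per channel by a random factor in [0.5, 1.5], plus a clean reference-ECG
  channel. The RR jitter matters: it decorrelates atrial phase from beat
  timing, which is what makes average-beat subtraction valid.
* **Noise**: white Gaussian (default σ = 0.05 against unit-amplitude
  sources, i.e. high but realistic SNR after the inverse solution's
  smoothing) and a 50 Hz mains sinusoid (default amplitude 0.02) with
  random phase per channel.

All randomness flows from one scenario seed fanned out per stage
(CRC-keyed `SeedSequence`), so identical scenarios are byte-identical.

What the generator does **not** emulate: rotors, wavebreak and true
fibrillatory conduction; anatomically realistic torso/atrial geometry and
inhomogeneous conductivities; inverse-solution artifacts in the VEGMs;
electrode contact noise and baseline wander; beat-morphology variability
beyond amplitude scaling. Passing tests therefore demonstrate that the
implementation is correct and that the volume-conductor damping mechanism
behaves as theorized under controlled conditions — not that clinical
recordings will show effect sizes of any particular magnitude.

## Problem sizes

The test suite and the acceptance script use scaled scenarios — typically
48 atrial nodes, 24 torso electrodes and 20–30 s records (9–14 analysis
windows) — chosen so the full driver sweep and pipeline runs complete in
seconds while every window-level statistic still has support; the default
scenario (256 nodes, 64 electrodes, 60 s) is what a study-scale synthetic
run would use. The qualitative conclusions (driver recovery, damping
direction and monotonicity) are size-independent in this model because the
driver/background weight shares in the lead field, not the node count,
determine them.

## Known limitations

* The moving-average band-pass has a gentle upper roll-off; analyses
  sensitive to 20–50 Hz content should check the documented response.
* The F-ratio independence argument is approximate for the Welch
  estimator, whose averaged sub-segments correlate neighboring native
  bins slightly.
* The harmonic-classification rule is a documented in-house criterion;
  borderline fundamentals close to the 1 Hz or 4 Hz search floors can
  flip labels between the cardiac and fibrillatory categories.
* The exponential difference-trend form is a modelling choice; with few
  populated bins (< 6) its parameters are weakly identified even when the
  fit's R² is high.
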