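# afdfmap

Dominant-frequency (DF) mapping of atrial fibrillation from simultaneous
intracardiac and body-surface recordings.

During atrial fibrillation (AF) the atria activate at fibrillatory rates of
roughly 4–10 Hz. The *dominant frequency* of a signal window is the
frequency of maximum spectral power in that band, and sites hosting the
*highest* DF (HDF) over the atrium are candidate AF drivers. Clinically it
is attractive to read these frequencies non-invasively from dense
body-surface mapping (BSM) electrode arrays — but the torso volume
conductor acts as a spatial low-pass: it mixes contributions from the whole
atrium, damping fast activity confined to small areas relative to slower
activity covering large areas, so torso-surface HDF systematically
underestimates the endocardial HDF, and increasingly so the faster the
endocardial driver.

`afdfmap` is a tested, reusable pipeline for quantifying exactly that
effect, for users analysing paired atrial virtual-electrogram (VEGM) and
BSM recordings — or studying the methodology itself on synthetic data with
known ground truth.

## What it computes

For each channel and 4 s analysis window (50% overlap, Hamming taper,
Welch or FFT estimator, zero-padded to a 0.05 Hz grid):

* **DF** — arg-max of power Y[f] in 4–10 Hz;
* **organization index** —

  ```
       Σ_{|f − f_DF| ≤ k} Y[f]  +  Σ_{n≥2} Σ_{|f − n·f_DF| ≤ k} Y[f]
  OI = ────────────────────────────────────────────────────────────
                        Σ_{f_l ≤ f ≤ f_h} Y[f]
  ```

  with half-width k = 0.375 Hz, harmonics counted while n·f_DF + k ≤ f_h,
  band f_l = 0 to f_h = 20 Hz. OI ∈ [0, 1] measures how completely the DF
  peak and its harmonics dominate the spectrum;
* **F-ratio peak test** — power at the peak over the mean power of the
  10 neighboring frequencies on each side, significant when it exceeds the
  upper-5% point of F(2, 2(F−1)) with F = 21, i.e. 3.23; non-significant
  peaks are checked for being harmonics of a slower cardiac or fibrillatory
  rate and such windows are excluded;
* **HDF and hosting area** — per window and dataset, the maximum DF over
  channels whose OI exceeds a threshold (grid 0–1, step 0.1); the hosting
  area is every channel with DF within 0.25 Hz below the HDF;
* **paired difference analysis** — per-window BSM HDF − VEGM HDF, binned
  by VEGM HDF in 0.5 Hz bins, with per-bin median/IQR and an exponential
  trend d(f) = −a·exp(b·(f − f₀)) + c fitted by Levenberg–Marquardt;
* **HDF-area distributions** — atrial hosting-area percentages for windows
  where the torso agrees with the atrium (|diff| ≤ 0.5 Hz) versus not,
  compared with a rank-sum test.

Upstream, the package provides EDF/BDF and delimited-matrix loading,
polyphase resampling to 512 Hz, a zero-phase 2–50 Hz moving-average
band-pass, rejection of channels with > 0.5% of spectral power at 50 Hz
mains, reference-lead cross-correlation alignment, and QRS-T cancellation
by average-beat template subtraction.

A synthetic generator (`afdfmap.synthetic`) produces paired recordings with
full ground truth: harmonic-series atrial sources with a compact fast
driver patch on a slower background, an inverse-distance lead-field
projection to torso electrodes, a shared ventricular far-field beat train,
mains and white noise.

## Worked example

```python
import numpy as np
from afdfmap import RunConfig, SyntheticScenario, run_pipeline

scn = SyntheticScenario(n_atrial_nodes=64, n_torso_electrodes=32,
                        duration_s=30.0, driver_freq=9.0, seed=42)
report = run_pipeline(RunConfig(scenario=scn, seed=42))

print("windows analysed:      ", len(report.pairs))
print("median atrial HDF (Hz):", np.median([p.vegm.hdf for p in report.pairs]))
print("median torso  HDF (Hz):", np.median([p.bsm.hdf for p in report.pairs]))
print("median BSM-VEGM (Hz):  ", report.difference.records['diff'].median())
print(report.difference.bins.to_string(index=False))
```

prints

```
windows analysed:       14
median atrial HDF (Hz): 9.05
median torso  HDF (Hz): 6.0
median BSM-VEGM (Hz):   -3.0250000000000004
 bin_center  median  iqr  count
       9.25  -3.025 0.05   14
```

The scenario places a 9 Hz driver on 5% of the atrium over a 6 Hz
background. The atrial side recovers the driver (HDF ≈ 9 Hz, the small
deviation coming from the simulated cycle-length jitter), while every torso
electrode is dominated by the large slow background (HDF = 6 Hz): the
volume conductor hides the small fast driver, giving a median torso−atrial
difference of about −3 Hz, collected here in the single 9.25 Hz VEGM-HDF
bin.

The same run is available from the shell:

```sh
afdfmap compare --config run.yaml --seed 42 --out results/run1
afdfmap report results/run1
```

with `simulate`, `preprocess` and `analyze` verbs for the individual
stages.

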