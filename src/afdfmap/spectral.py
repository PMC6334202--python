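"""Per-window power spectra and spectral metrics for fibrillatory signals.

For each 4 s analysis window of each channel this module computes a
zero-padded power spectrum on a uniform 0.05 Hz grid and derives

* the dominant frequency (DF): the frequency of maximum power in 4–10 Hz;
* the organization index (OI): the fraction of 0–20 Hz spectral power that
  lies within ±k (default 0.375 Hz) of the DF and of its integer harmonics,

      OI = [ Σ_{|f−f_DF|≤k} Y[f] + Σ_n Σ_{|f−n·f_DF|≤k} Y[f] ] / Σ_{f_l..f_h} Y[f],

  harmonics counted while n·f_DF + k ≤ f_h, overlapping windows counted once;
* an F-ratio peak-significance test: power at the peak over the mean power
  of the 10 neighboring frequencies on each side, compared with the upper-5%
  point of an F distribution with 2 and 2(F−1) = 40 degrees of freedom
  (F = 21 frequencies), critical value 3.23;
* a harmonic classification for non-significant peaks: the peak is labelled
  a harmonic of the strongest sub-peak found in [1 Hz, DF) (cardiac cycle
  rate) or [4 Hz, DF) (slower fibrillatory driver).

Two estimators are provided: ``welch`` averages Hamming-tapered half-window
sub-segments at 50% overlap inside each analysis window; ``fft`` uses a
single Hamming-tapered periodogram of the whole window. Both are
zero-padded to the 0.05 Hz grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .errors import UndefinedOIError, ValidationError
from .signal_io import MultichannelRecording

HARMONIC_NONE = "none"
HARMONIC_CARDIAC = "cardiac-harmonic"
HARMONIC_AF = "af-harmonic"


@dataclass
class SpectralConfig:
    """Parameters of the spectral pipeline.

    window_s : analysis window length in seconds.
    overlap_frac : overlap between consecutive analysis windows.
    taper : taper applied to (sub-)segments.
    bin_width : spectral grid spacing in Hz after zero-padding.
    df_band : (low, high) Hz band searched for the dominant frequency.
    oi_halfwidth : half-width k in Hz of the DF/harmonic integration windows.
    oi_band : (f_l, f_h) Hz denominator band of the organization index.
    n_neighbors : neighbor frequencies per side in the F-ratio test.
    f_crit : F-ratio critical value; None computes the upper-5% point of
        F(2, 2(F−1)) with F = 2·n_neighbors + 1 (3.23 for the default 10).
    estimator : ``welch`` or ``fft``.
    neighbor_spacing : ``native`` spaces F-ratio neighbors at the
        pre-padding resolution (where bins are approximately independent);
        ``padded`` uses contiguous zero-padded bins.
    refine_harmonics : if True, each OI harmonic window is re-centered on
        the local spectral maximum within ±k of the integer multiple.
    """

    window_s: float = 4.0
    overlap_frac: float = 0.5
    taper: str = "hamming"
    bin_width: float = 0.05
    df_band: tuple[float, float] = (4.0, 10.0)
    oi_halfwidth: float = 0.375
    oi_band: tuple[float, float] = (0.0, 20.0)
    n_neighbors: int = 10
    f_crit: float | None = None
    estimator: str = "welch"
    neighbor_spacing: str = "native"
    refine_harmonics: bool = False

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be positive")
        if self.oi_halfwidth <= 0:
            raise ValidationError("oi_halfwidth must be positive")
        if self.n_neighbors < 1:
            raise ValidationError("n_neighbors must be >= 1")
        if self.estimator not in ("welch", "fft"):
            raise ValidationError(f"unknown estimator {self.estimator!r}")
        if self.neighbor_spacing not in ("native", "padded"):
            raise ValidationError(
                f"unknown neighbor_spacing {self.neighbor_spacing!r}"
            )
        if not (0 <= self.overlap_frac < 1):
            raise ValidationError("overlap_frac must be in [0, 1)")
        if self.df_band[0] >= self.df_band[1]:
            raise ValidationError("df_band must be increasing")

    @property
    def n_frequencies(self) -> int:
        """Number of frequencies entering the F-ratio (peak + neighbors)."""
        return 2 * self.n_neighbors + 1

    def critical_value(self) -> float:
        """F-ratio significance threshold: the configured value, or the
        upper-5% quantile of F(2, 2(F−1)) with F = n_frequencies."""
        if self.f_crit is not None:
            return self.f_crit
        return float(stats.f.ppf(0.95, 2, 2 * (self.n_frequencies - 1)))

    def native_spacing(self, fs: float) -> float:
        """Pre-zero-padding spectral resolution in Hz for the estimator."""
        seg_s = self.window_s / 2 if self.estimator == "welch" else self.window_s
        return 1.0 / seg_s


@dataclass
class WindowSpectrum:
    """Power spectrum of one channel-window on a uniform frequency grid."""

    channel: str
    window: int
    freqs: np.ndarray
    power: np.ndarray
    native_spacing: float | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ValidationError("freqs and power must be 1-D and same shape")
        d = np.diff(self.freqs)
        if d.size and (np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-9)):
            raise ValidationError("freqs must be strictly increasing and uniform")
        if np.any(self.power < 0):
            raise ValidationError("power must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class FRatioResult:
    """Outcome of the F-ratio peak-significance test."""

    f_ratio: float
    significant: bool
    peak_freq: float
    neighbor_freqs: np.ndarray
    critical_value: float


@dataclass
class DFResult:
    """Per channel-window spectral metrics."""

    channel: str
    window: int
    df: float
    peak_power: float
    oi: float
    f_ratio: float
    significant: bool
    harmonic_status: str = HARMONIC_NONE
    fundamental: float | None = None


# ---------------------------------------------------------------------------
# Windowing and spectra
# ---------------------------------------------------------------------------

def window_segments(
    rec: MultichannelRecording, cfg: SpectralConfig
) -> list[tuple[int, tuple[int, int]]]:
    """Half-open sample ranges of the analysis windows.

    Windows have length ``window_s·fs`` and hop ``window_s·(1−overlap)·fs``;
    a trailing partial window is dropped.
    """
    win = int(round(cfg.window_s * rec.fs))
    hop = int(round(cfg.window_s * (1 - cfg.overlap_frac) * rec.fs))
    if hop < 1:
        raise ValidationError("hop must be at least one sample")
    if rec.n_samples < win:
        warnings.warn("recording shorter than one analysis window")
        return []
    n_win = (rec.n_samples - win) // hop + 1
    return [(i, (i * hop, i * hop + win)) for i in range(n_win)]


def _spectrum_matrix(
    segments: np.ndarray, fs: float, cfg: SpectralConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectra for a (channels × window-samples) block."""
    if not np.all(np.isfinite(segments)):
        raise ValidationError("segments contain non-finite samples")
    nfft = int(round(fs / cfg.bin_width))
    if cfg.estimator == "welch":
        nperseg = int(round(cfg.window_s * fs / 2))
        freqs, pxx = sps.welch(
            segments,
            fs=fs,
            window=cfg.taper,
            nperseg=nperseg,
            noverlap=nperseg // 2,
            nfft=nfft,
            detrend=False,
            axis=-1,
        )
    else:
        freqs, pxx = sps.periodogram(
            segments, fs=fs, window=cfg.taper, nfft=nfft, detrend=False, axis=-1
        )
    return freqs, np.atleast_2d(pxx)


def compute_spectrum(
    segment: np.ndarray,
    fs: float,
    cfg: SpectralConfig | None = None,
    channel: str = "",
    window: int = 0,
) -> WindowSpectrum:
    """Spectrum of one channel-window on the zero-padded ``bin_width`` grid.

    The transform length is ``fs / bin_width`` samples, so the grid spacing
    is exactly ``bin_width`` (0.05 Hz by default for 4 s windows at 512 Hz).
    """
    cfg = cfg or SpectralConfig()
    segment = np.asarray(segment, dtype=float)
    expected = int(round(cfg.window_s * fs))
    if segment.ndim != 1 or segment.size != expected:
        raise ValidationError(
            f"segment must be 1-D of length window_s*fs = {expected}, "
            f"got shape {segment.shape}"
        )
    freqs, pxx = _spectrum_matrix(segment[None, :], fs, cfg)
    return WindowSpectrum(
        channel, window, freqs, pxx[0], native_spacing=cfg.native_spacing(fs)
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

_TOL_FRAC = 1e-6  # grid-inclusion tolerance as a fraction of bin width


def find_df(
    spec: WindowSpectrum, band: tuple[float, float] = (4.0, 10.0)
) -> tuple[float, float]:
    """Dominant frequency: arg-max of power within the closed band.

    Ties break toward the lower frequency.
    """
    tol = spec.bin_width * _TOL_FRAC
    mask = (spec.freqs >= band[0] - tol) & (spec.freqs <= band[1] + tol)
    if not mask.any():
        raise ValidationError(f"band {band} outside the spectral grid")
    idx = np.flatnonzero(mask)
    best = idx[int(np.argmax(spec.power[idx]))]
    return float(spec.freqs[best]), float(spec.power[best])


def _oi_numerator_mask(
    freqs: np.ndarray,
    power: np.ndarray,
    df: float,
    k: float,
    f_h: float,
    refine: bool,
) -> np.ndarray:
    tol = (freqs[1] - freqs[0]) * _TOL_FRAC
    mask = np.abs(freqs - df) <= k + tol
    n = 2
    while n * df + k <= f_h + tol:
        h = n * df
        if refine:
            near = np.abs(freqs - h) <= k + tol
            if near.any():
                idx = np.flatnonzero(near)
                h = float(freqs[idx[int(np.argmax(power[idx]))]])
        mask |= np.abs(freqs - h) <= k + tol
        n += 1
    return mask


def organization_index(
    spec: WindowSpectrum, df: float, cfg: SpectralConfig | None = None
) -> float:
    """Organization index of a spectrum with respect to its DF.

    Numerator: power within ±k of the DF plus, for every harmonic
    ``n·DF`` (n ≥ 2) with ``n·DF + k ≤ f_h``, power within ±k of it —
    each bin counted once. Denominator: power over ``[f_l, f_h]``.
    Result clipped to [0, 1].
    """
    cfg = cfg or SpectralConfig()
    k = cfg.oi_halfwidth
    f_l, f_h = cfg.oi_band
    tol = spec.bin_width * _TOL_FRAC
    den_mask = (spec.freqs >= f_l - tol) & (spec.freqs <= f_h + tol)
    den = spec.power[den_mask].sum()
    if den <= 0:
        raise UndefinedOIError("total spectral power in the OI band is zero")
    num_mask = _oi_numerator_mask(
        spec.freqs, spec.power, df, k, f_h, cfg.refine_harmonics
    )
    num = spec.power[num_mask & den_mask].sum()
    return float(np.clip(num / den, 0.0, 1.0))


def f_ratio_test(
    spec: WindowSpectrum, peak: float, cfg: SpectralConfig | None = None
) -> FRatioResult:
    """Peak power over the mean power of ``n_neighbors`` frequencies on each
    side, tested against the F(2, 2(F−1)) critical value.

    With ``neighbor_spacing='native'`` the neighbors are taken every
    ``native_spacing / bin_width``-th zero-padded bin, i.e. at the
    pre-padding resolution where bins are approximately independent;
    ``'padded'`` uses contiguous bins. Neighbors falling off the grid are
    truncated with a warning.
    """
    cfg = cfg or SpectralConfig()
    peak_idx = int(np.argmin(np.abs(spec.freqs - peak)))
    if cfg.neighbor_spacing == "native":
        native = spec.native_spacing or spec.bin_width
        step = max(int(round(native / spec.bin_width)), 1)
    else:
        step = 1
    idx = []
    truncated = False
    for j in range(1, cfg.n_neighbors + 1):
        for sign in (-1, 1):
            i = peak_idx + sign * j * step
            if 0 <= i < spec.freqs.size:
                idx.append(i)
            else:
                truncated = True
    if truncated:
        warnings.warn(
            "F-ratio neighbors extend beyond the spectral grid; truncated"
        )
    if not idx:
        raise ValidationError("no usable neighbor bins for the F-ratio test")
    idx = np.array(sorted(idx))
    neigh_mean = float(spec.power[idx].mean())
    peak_power = float(spec.power[peak_idx])
    if neigh_mean > 0:
        f_ratio = peak_power / neigh_mean
    else:
        f_ratio = np.inf if peak_power > 0 else 1.0
    crit = cfg.critical_value()
    return FRatioResult(
        f_ratio=float(f_ratio),
        significant=bool(f_ratio > crit),
        peak_freq=float(spec.freqs[peak_idx]),
        neighbor_freqs=spec.freqs[idx],
        critical_value=crit,
    )


def classify_harmonic(
    spec: WindowSpectrum, hdf: float, cfg: SpectralConfig | None = None
) -> tuple[str, float | None]:
    """Decide whether a non-significant peak is a harmonic of a slower rate.

    Searches for the strongest frequency g in [1 Hz, hdf) (cardiac cycle
    rate) and in [4 Hz, hdf) (slower fibrillatory driver); ``hdf`` is
    labelled a harmonic of g when it lies within ±k of an integer multiple
    of g and g carries at least as much power. The fibrillatory-band search
    takes precedence (``af-harmonic``); otherwise ``cardiac-harmonic``;
    otherwise ``none``.
    """
    cfg = cfg or SpectralConfig()
    k = cfg.oi_halfwidth
    tol = spec.bin_width * _TOL_FRAC
    if hdf <= 1.0:
        return HARMONIC_NONE, None
    peak_idx = int(np.argmin(np.abs(spec.freqs - hdf)))
    peak_power = spec.power[peak_idx]

    def strongest(lo: float) -> float | None:
        mask = (spec.freqs >= lo - tol) & (spec.freqs < hdf - spec.bin_width / 2)
        if not mask.any():
            return None
        idx = np.flatnonzero(mask)
        return float(spec.freqs[idx[int(np.argmax(spec.power[idx]))]])

    def is_fundamental(g: float | None) -> bool:
        if g is None or g <= 0:
            return False
        g_idx = int(np.argmin(np.abs(spec.freqs - g)))
        if spec.power[g_idx] < peak_power:
            return False
        n = int(round(hdf / g))
        return n >= 2 and abs(hdf - n * g) <= k + tol

    g4 = strongest(4.0)
    if is_fundamental(g4):
        return HARMONIC_AF, g4
    g1 = strongest(1.0)
    if is_fundamental(g1):
        return HARMONIC_CARDIAC, g1
    return HARMONIC_NONE, None


# ---------------------------------------------------------------------------
# Recording-level driver
# ---------------------------------------------------------------------------

def analyze_segment(
    spec: WindowSpectrum, cfg: SpectralConfig | None = None
) -> DFResult:
    """DF, OI, F-ratio and harmonic status for one channel-window spectrum."""
    cfg = cfg or SpectralConfig()
    df, peak_power = find_df(spec, cfg.df_band)
    oi = organization_index(spec, df, cfg)
    fr = f_ratio_test(spec, df, cfg)
    status, fundamental = (HARMONIC_NONE, None)
    if not fr.significant:
        status, fundamental = classify_harmonic(spec, df, cfg)
    return DFResult(
        channel=spec.channel,
        window=spec.window,
        df=df,
        peak_power=peak_power,
        oi=oi,
        f_ratio=fr.f_ratio,
        significant=fr.significant,
        harmonic_status=status,
        fundamental=fundamental,
    )


def analyze_recording(
    rec: MultichannelRecording,
    cfg: SpectralConfig | None = None,
    roles: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Tidy table of per channel-window spectral metrics.

    Only channels with ``valid_mask`` set (and, if ``roles`` is given, a
    matching role) are analyzed. Columns: channel, window, df, peak_power,
    oi, f_ratio, significant, harmonic_status, fundamental.
    """
    cfg = cfg or SpectralConfig()
    keep = rec.valid_mask.copy()
    if roles is not None:
        roleset = set(roles)
        keep &= np.array([r in roleset for r in rec.roles])
    sub = rec.select(keep)
    rows = []
    native = cfg.native_spacing(rec.fs)
    for widx, (start, stop) in window_segments(rec, cfg):
        freqs, pxx = _spectrum_matrix(sub.samples[:, start:stop], rec.fs, cfg)
        for ci, label in enumerate(sub.labels):
            spec = WindowSpectrum(label, widx, freqs, pxx[ci], native)
            rows.append(analyze_segment(spec, cfg).__dict__)
    columns = [
        "channel", "window", "df", "peak_power", "oi",
        "f_ratio", "significant", "harmonic_status", "fundamental",
    ]
    return pd.DataFrame(rows, columns=columns)
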