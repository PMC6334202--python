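"""Synthetic atrial-source and volume-conductor simulator.

Generates paired atrial-node and torso-electrode recordings with the
statistical structure the analysis pipeline assumes, together with full
ground truth:

* atrial nodes on a spherical patch, each emitting a quasi-periodic
  harmonic-series oscillator in the fibrillatory 4–10 Hz band — a compact
  fast "driver" patch on a slower large-area background, phased as
  traveling waves from per-region foci;
* a torso forward projection through an inverse-distance lead field with
  neighborhood smoothing: a memoryless linear spatial mixing that dampens
  small-area fast sources relative to the large-area background, the
  volume-conductor mechanism under study;
* a shared ventricular far-field QRS-T beat train (plus a clean
  reference-ECG channel for detection and alignment);
* 50 Hz mains contamination and additive white noise.

Everything is driven by one scenario seed; identical scenarios produce
byte-identical recordings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .signal_io import (
    ROLE_ATRIAL,
    ROLE_REFERENCE,
    ROLE_TORSO,
    MultichannelRecording,
)

REFERENCE_LABEL = "ECG-I"


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic recording pair.

    Geometry: atrial nodes on a unit-sphere patch (spherical cap of
    half-angle ``atrial_cap_deg``), torso electrodes on a concentric shell
    of radius ``torso_radius``. The driver patch is the
    ``driver_area_frac`` fraction of nodes nearest the patch pole.
    """

    n_atrial_nodes: int = 256
    n_torso_electrodes: int = 64
    background_freq: float = 6.0
    driver_freq: float = 9.0
    driver_area_frac: float = 0.05
    harmonic_amps: tuple[float, ...] = (1.0, 0.4, 0.15)
    leadfield_exponent: float = 2.0
    leadfield_smoothing: float = 0.3  # neighborhood radius (chord length)
    ventricular_rate: float = 1.0
    ventricular_amp: float = 1.0
    ventricular_jitter: float = 0.05  # beat-interval SD as fraction of interval
    mains_amp: float = 0.02
    mains_freq: float = 50.0
    noise_sigma: float = 0.05
    freq_jitter: float = 0.01  # cycle-length jitter as fraction of frequency
    duration_s: float = 60.0
    fs: float = 512.0
    atrial_radius: float = 1.0
    torso_radius: float = 2.0
    atrial_cap_deg: float = 135.0
    wave_number: float = 0.5  # traveling-wave phase (rad) per radian of arc
    seed: int = 0

    def __post_init__(self) -> None:
        if not (4.0 <= self.background_freq < self.driver_freq <= 10.0):
            raise ValidationError(
                "need 4 <= background_freq < driver_freq <= 10"
            )
        if not (0 <= self.driver_area_frac < 0.5):
            raise ValidationError("driver_area_frac must be in [0, 0.5)")
        if self.ventricular_rate >= 3.0:
            raise ValidationError("ventricular_rate must be below 3 Hz")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValidationError("duration_s and fs must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def rng_for(self, stage: str) -> np.random.Generator:
        """Stage-specific generator fanned out from the scenario seed."""
        key = zlib.crc32(stage.encode()) % (2**31)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _fibonacci_cap(n: int, radius: float, cap_deg: float) -> np.ndarray:
    """n roughly-equidistant points on a spherical cap about +z."""
    i = np.arange(n)
    z_min = np.cos(np.deg2rad(cap_deg))
    z = 1.0 - (1.0 - z_min) * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atrial_geometry(scn: SyntheticScenario) -> np.ndarray:
    return _fibonacci_cap(scn.n_atrial_nodes, scn.atrial_radius, scn.atrial_cap_deg)


def torso_geometry(scn: SyntheticScenario) -> np.ndarray:
    return _fibonacci_cap(scn.n_torso_electrodes, scn.torso_radius, 180.0)


def driver_node_indices(scn: SyntheticScenario, coords: np.ndarray) -> np.ndarray:
    """Indices of the driver patch: the nodes nearest the patch pole.

    Empty when ``driver_area_frac`` is 0 (uniform background field)."""
    n_driver = int(round(scn.driver_area_frac * scn.n_atrial_nodes))
    if scn.driver_area_frac > 0:
        n_driver = max(n_driver, 1)
    pole = np.array([0.0, 0.0, scn.atrial_radius])
    dist = np.linalg.norm(coords - pole, axis=1)
    return np.argsort(dist)[:n_driver]


# ---------------------------------------------------------------------------
# Sources
# ---------------------------------------------------------------------------

def simulate_atrial_sources(
    scn: SyntheticScenario,
) -> tuple[MultichannelRecording, dict[str, float]]:
    """Atrial-node recording plus the ground-truth node → frequency map.

    Each node emits ``Σ_h amp_h · cos(h·φ_n(t))`` where dφ_n/dt tracks the
    node's assigned frequency (driver or background) modulated by slow,
    seeded cycle-length jitter; initial phases follow a traveling wave
    radiating from the region's focus.
    """
    coords = atrial_geometry(scn)
    n = scn.n_atrial_nodes
    labels = [f"A{i:04d}" for i in range(n)]
    driver_idx = driver_node_indices(scn, coords)
    freqs = np.full(n, scn.background_freq)
    freqs[driver_idx] = scn.driver_freq

    # traveling-wave initial phase: arc distance from the region focus
    unit = coords / scn.atrial_radius
    pole = np.array([0.0, 0.0, 1.0])
    driver_focus = unit[driver_idx[0]] if driver_idx.size else pole
    background_focus = -driver_focus
    phase0 = np.empty(n)
    if driver_idx.size:
        arc = np.arccos(np.clip(unit[driver_idx] @ driver_focus, -1, 1))
        phase0[driver_idx] = -scn.wave_number * arc
    bg_mask = np.ones(n, dtype=bool)
    bg_mask[driver_idx] = False
    arc = np.arccos(np.clip(unit[bg_mask] @ background_focus, -1, 1))
    phase0[bg_mask] = -scn.wave_number * arc

    t_n = scn.n_samples
    rng = scn.rng_for("atrial-sources")
    if scn.freq_jitter > 0:
        # slow (<~1 Hz) zero-mean frequency modulation, unit variance
        raw = rng.standard_normal((n, t_n))
        smooth = gaussian_filter1d(raw, sigma=scn.fs / 4, axis=1, mode="reflect")
        sd = smooth.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        modulation = 1.0 + scn.freq_jitter * smooth / sd
    else:
        modulation = np.ones((1, t_n))
    inst_freq = freqs[:, None] * modulation
    phase = phase0[:, None] + 2 * np.pi * np.cumsum(inst_freq, axis=1) / scn.fs

    samples = np.zeros((n, t_n))
    for h, amp in enumerate(scn.harmonic_amps, start=1):
        samples += amp * np.cos(h * phase)

    rec = MultichannelRecording(
        samples, scn.fs, labels, [ROLE_ATRIAL] * n, coords=coords
    )
    return rec, dict(zip(labels, freqs.tolist()))


# ---------------------------------------------------------------------------
# Volume conductor
# ---------------------------------------------------------------------------

def build_leadfield(
    scn: SyntheticScenario,
    atrial_coords: np.ndarray | None = None,
    torso_coords: np.ndarray | None = None,
) -> np.ndarray:
    """Electrode × node forward-weight matrix.

    ``w(e, n) ∝ 1 / distance(e, n)^exponent``, spatially smoothed over each
    node's neighborhood (nodes within ``leadfield_smoothing`` of one
    another), rows normalized to sum to 1. All weights are non-negative.
    """
    if atrial_coords is None:
        atrial_coords = atrial_geometry(scn)
    if torso_coords is None:
        torso_coords = torso_geometry(scn)
    d = cdist(torso_coords, atrial_coords)
    d = np.maximum(d, 1e-6)
    w = d**-scn.leadfield_exponent
    if scn.leadfield_smoothing > 0:
        nn = cdist(atrial_coords, atrial_coords) <= scn.leadfield_smoothing
        smooth = nn / nn.sum(axis=1, keepdims=True)
        w = w @ smooth.T
    w /= w.sum(axis=1, keepdims=True)
    return w


def forward_project(
    atrial: MultichannelRecording,
    leadfield: np.ndarray,
    torso_coords: np.ndarray | None = None,
) -> MultichannelRecording:
    """Torso recording as the memoryless linear mixing of the atrial sources."""
    leadfield = np.asarray(leadfield, dtype=float)
    if leadfield.ndim != 2 or leadfield.shape[1] != atrial.n_channels:
        raise ValidationError(
            f"leadfield shape {leadfield.shape} does not match "
            f"{atrial.n_channels} atrial channels"
        )
    samples = leadfield @ atrial.samples
    n_e = leadfield.shape[0]
    labels = [f"T{i:04d}" for i in range(n_e)]
    return MultichannelRecording(
        samples, atrial.fs, labels, [ROLE_TORSO] * n_e, coords=torso_coords
    )


# ---------------------------------------------------------------------------
# Ventricular far-field, mains and noise
# ---------------------------------------------------------------------------

def qrst_waveform(t: np.ndarray) -> np.ndarray:
    """Stylized QRS-T complex on t in seconds relative to the R peak."""

    def g(center, width):
        return np.exp(-0.5 * ((t - center) / width) ** 2)

    return (
        -0.15 * g(-0.040, 0.010)
        + 1.00 * g(0.0, 0.012)
        - 0.25 * g(0.040, 0.012)
        + 0.35 * g(0.300, 0.050)
    )


def make_beat_times(
    scn: SyntheticScenario, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Jittered R-peak times (s) covering the recording."""
    rng = rng or scn.rng_for("beat-times")
    mean_rr = 1.0 / scn.ventricular_rate
    times, t = [], 0.5 * mean_rr
    while t < scn.duration_s - 0.5:
        times.append(t)
        rr = mean_rr * (1.0 + scn.ventricular_jitter * rng.standard_normal())
        t += max(rr, 0.35)
    return np.asarray(times)


def add_ventricular_farfield(
    rec: MultichannelRecording,
    rate: float,
    amplitude: float,
    jitter: float = 0.05,
    beat_times: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    duration_s: float | None = None,
) -> tuple[MultichannelRecording, np.ndarray]:
    """Add a shared QRS-T beat train plus a clean reference-ECG channel.

    Every channel receives the same beat train scaled by a random
    per-channel factor in [0.5, 1.5]; an appended ``ECG-I`` channel carries
    the unscaled clean train for R-peak detection and alignment. Returns
    the augmented recording and the ground-truth R-peak sample indices.
    With ``amplitude == 0`` the recording is returned unchanged.
    """
    if rate >= 3.0:
        raise ValidationError("ventricular rate must be below 3 Hz")
    if amplitude == 0:
        return rec.copy(), np.array([], dtype=int)
    rng = rng or np.random.default_rng(0)
    if beat_times is None:
        scn_like = SyntheticScenario(
            ventricular_rate=rate,
            ventricular_jitter=jitter,
            duration_s=duration_s or rec.duration,
            fs=rec.fs,
        )
        beat_times = make_beat_times(scn_like, rng)
    t = np.arange(rec.n_samples) / rec.fs
    train = np.zeros(rec.n_samples)
    for bt in beat_times:
        lo = max(int((bt - 0.15) * rec.fs), 0)
        hi = min(int((bt + 0.55) * rec.fs), rec.n_samples)
        train[lo:hi] += qrst_waveform(t[lo:hi] - bt)
    scales = amplitude * rng.uniform(0.5, 1.5, rec.n_channels)
    out = rec.copy()
    out.samples = out.samples + scales[:, None] * train[None, :]
    out.samples = np.vstack([out.samples, train[None, :]])
    out.labels = list(out.labels) + [REFERENCE_LABEL]
    out.roles = list(out.roles) + [ROLE_REFERENCE]
    out.valid_mask = np.append(out.valid_mask, True)
    if out.coords is not None:
        out.coords = np.vstack([out.coords, np.zeros((1, 3))])
    r_peaks = np.round(beat_times * rec.fs).astype(int)
    return out, r_peaks


def add_noise(
    rec: MultichannelRecording,
    sigma: float,
    mains_amp: float = 0.0,
    mains_freq: float = 50.0,
    rng: np.random.Generator | None = None,
    mains_channels: np.ndarray | None = None,
) -> MultichannelRecording:
    """Add seeded white Gaussian noise and a mains sinusoid.

    ``mains_channels`` restricts the mains contamination to a channel-index
    subset. With ``sigma == 0`` and ``mains_amp == 0`` this is the identity.
    """
    out = rec.copy()
    if sigma == 0 and mains_amp == 0:
        return out
    rng = rng or np.random.default_rng(0)
    if sigma > 0:
        out.samples = out.samples + sigma * rng.standard_normal(out.samples.shape)
    if mains_amp > 0:
        t = np.arange(rec.n_samples) / rec.fs
        idx = (
            np.arange(rec.n_channels)
            if mains_channels is None
            else np.asarray(mains_channels)
        )
        phases = rng.uniform(0, 2 * np.pi, idx.size)
        for i, ph in zip(idx, phases):
            out.samples[i] += mains_amp * np.sin(2 * np.pi * mains_freq * t + ph)
    return out


# ---------------------------------------------------------------------------
# Full scenario
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Everything one scenario produces: the two recordings and ground truth."""

    atrial: MultichannelRecording
    torso: MultichannelRecording
    leadfield: np.ndarray
    node_freqs: dict[str, float]
    driver_labels: list[str]
    r_peaks: np.ndarray
    scenario: SyntheticScenario


def simulate_scenario(scn: SyntheticScenario) -> SimulationResult:
    """Run the full generator: sources → lead field → torso projection →
    shared ventricular far-field → mains + noise."""
    atrial, node_freqs = simulate_atrial_sources(scn)
    coords = atrial.coords
    torso_coords = torso_geometry(scn)
    leadfield = build_leadfield(scn, coords, torso_coords)
    torso = forward_project(atrial, leadfield, torso_coords)

    beat_rng = scn.rng_for("beat-times")
    beat_times = make_beat_times(scn, beat_rng)
    r_peaks = np.array([], dtype=int)
    if scn.ventricular_amp > 0:
        atrial, r_peaks = add_ventricular_farfield(
            atrial, scn.ventricular_rate, scn.ventricular_amp,
            beat_times=beat_times, rng=scn.rng_for("vf-atrial"),
        )
        torso, _ = add_ventricular_farfield(
            torso, scn.ventricular_rate, scn.ventricular_amp,
            beat_times=beat_times, rng=scn.rng_for("vf-torso"),
        )
    atrial = add_noise(
        atrial, scn.noise_sigma, scn.mains_amp, scn.mains_freq,
        rng=scn.rng_for("noise-atrial"),
    )
    torso = add_noise(
        torso, scn.noise_sigma, scn.mains_amp, scn.mains_freq,
        rng=scn.rng_for("noise-torso"),
    )
    driver_labels = [
        atrial.labels[i] for i in driver_node_indices(scn, coords)
    ]
    return SimulationResult(
        atrial=atrial,
        torso=torso,
        leadfield=leadfield,
        node_freqs=node_freqs,
        driver_labels=driver_labels,
        r_peaks=r_peaks,
        scenario=scn,
    )


def scenario_to_dict(scn: SyntheticScenario) -> dict:
    return asdict(scn)


def scenario_from_dict(data: dict) -> SyntheticScenario:
    data = dict(data)
    if "harmonic_amps" in data:
        data["harmonic_amps"] = tuple(data["harmonic_amps"])
    return SyntheticScenario(**data)
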