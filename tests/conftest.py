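import numpy as np
import pytest

from afdfmap.signal_io import MultichannelRecording, save_recording


def make_tone_recording(
    freqs, fs=512.0, duration=8.0, amps=None, roles=None, labels=None
):
    """Recording whose channels are pure cosines at the given frequencies."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    t = np.arange(int(round(duration * fs))) / fs
    amps = np.ones_like(freqs) if amps is None else np.asarray(amps, dtype=float)
    samples = amps[:, None] * np.cos(2 * np.pi * freqs[:, None] * t[None, :])
    n = len(freqs)
    labels = labels or [f"ch{i}" for i in range(n)]
    roles = roles or ["atrial-node"] * n
    return MultichannelRecording(samples, fs, labels, roles)


@pytest.fixture
def tone_recording():
    return make_tone_recording([6.0])


@pytest.fixture
def matrix_pair(tmp_path):
    """A 3-channel recording written in the canonical matrix + sidecar form."""
    rec = make_tone_recording([5.0, 6.0, 7.0], duration=2.0)
    data_path = tmp_path / "rec.txt"
    meta_path = tmp_path / "rec.yaml"
    save_recording(rec, data_path, meta_path)
    return rec, data_path, meta_path
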