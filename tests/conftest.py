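import numpy as np
import pytest

from nocturn import SimConfig, archetype, simulate_hypnogram, simulate_signals


@pytest.fixture(scope="session")
def nab_config():
    """Default-line config, shortened to 2 h for fast unit tests."""
    return archetype("NAB").apply().replace(n_hours=2.0, seed=7)


@pytest.fixture(scope="session")
def short_recording(nab_config):
    """2-h synthetic recording + ground-truth hypnogram (NAB line)."""
    hyp = simulate_hypnogram(nab_config)
    rec = simulate_signals(hyp, nab_config)
    return rec, hyp


def tone_recording(freq_hz, amplitude=50.0, n_epochs=4, fs=64.0,
                   channel="EEG2"):
    """Recording whose EEG is a pure sinusoid — spectral test input."""
    from nocturn import SignalRecording

    n = int(n_epochs * fs * 4)
    t = np.arange(n) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return SignalRecording(channels={channel: x, "EMG": np.zeros(n)},
                           sampling_rate_hz=fs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
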