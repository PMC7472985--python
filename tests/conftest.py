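import numpy as np
import pytest

from mibcigame import RawRun, SimConfig, simulate_run


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size run for fast tests: same structure, fewer trials
    and a lower (still Nyquist-safe) sampling rate."""
    return SimConfig(fs=128.0, n_trials=20, seed=11)


@pytest.fixture(scope="session")
def small_run(small_config):
    return simulate_run(small_config)


@pytest.fixture(scope="session")
def default_run():
    """One run at the study's full size (80 trials, 256 Hz)."""
    return simulate_run(SimConfig(seed=5))


def tone_run(freq, fs=256.0, dur=12.0, amp=1.0, n_channels=2, dc=0.0):
    """Single-tone RawRun for filter-response oracles."""
    t = np.arange(round(dur * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t) + dc
    data = np.tile(x, (n_channels, 1))
    return RawRun(
        data=data, fs=fs, trial_onsets=np.array([0]),
        labels=np.array(["left"], dtype=object),
        channel_names=tuple(f"ch{i}" for i in range(n_channels)),
    )


def tone_amplitude(x, freq, fs):
    """Amplitude of a sinusoidal component, measured on the interior of
    the signal (skipping filter edge transients) by projection onto the
    quadrature pair over an integer number of cycles."""
    n = len(x)
    skip = n // 4
    seg = x[skip:n - skip]
    cycles = int(np.floor(len(seg) * freq / fs))
    if cycles < 1:
        raise ValueError("signal too short for the requested frequency")
    m = round(cycles * fs / freq)
    seg = seg[:m]
    t = (np.arange(m) + skip) / fs
    a = 2.0 * np.mean(seg * np.cos(2 * np.pi * freq * t))
    b = 2.0 * np.mean(seg * np.sin(2 * np.pi * freq * t))
    return float(np.hypot(a, b))
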