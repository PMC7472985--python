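"""Synthetic lateralized motor-imagery EEG.

Generates multi-channel runs with the statistical structure a CSP + LDA
decoding chain relies on: a 1/f background, mu (8–12 Hz) and beta
(18–26 Hz) rhythms generated by one source per hemisphere and projected
onto a 16-electrode sensorimotor montage, and event-related
desynchronization (ERD) — a class-dependent attenuation of the rhythm
over the hemisphere contralateral to the imagined wrist movement during
the imagery window of each trial. Optional 50 Hz line interference and
high-amplitude artifact trials exercise the notch filter and the
rejection stage downstream.

The generator is purely statistical: band-limited Gaussian rhythms with
a fixed spatial spread, not a biophysical head model.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import ConfigError, DataError

#: Electrode montage over sensorimotor cortex (10/10 positions).
CHANNELS = (
    "FC5", "FC1", "FCz", "FC2", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP1", "CP2", "CP6",
)

#: Immediate montage neighbours of the two source electrodes; the
#: lateralized rhythm projects with weight 1 to C3/C4 and 0.5 to these.
_NEIGHBOURS = {
    "C3": ("C5", "C1", "FC5", "FC1", "CP5", "CP1"),
    "C4": ("C2", "C6", "FC2", "FC6", "CP2", "CP6"),
}

LEFT, RIGHT = "left", "right"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated run.

    Amplitudes are in µV (standard deviations of the respective
    processes). ``erd_depth`` is the fractional variance attenuation of
    the contralateral rhythm inside ``mi_window``: variance during
    imagery = (1 - erd_depth) × variance at rest.
    """

    n_channels: int = 16
    channel_names: tuple[str, ...] = CHANNELS
    fs: float = 256.0
    n_trials: int = 80
    trial_len: float = 9.0
    epoch_len: float = 8.0
    mi_window: tuple[float, float] = (2.0, 8.0)
    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (18.0, 26.0)
    erd_depth: float = 0.6
    erd_ramp: float = 0.25
    noise_exponent: float = 1.0
    background_std: float = 2.0
    mu_amp: float = 3.0
    beta_amp: float = 1.5
    line_amp: float = 0.0
    artifact_rate: float = 0.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_channels != len(self.channel_names):
            raise ConfigError(
                f"n_channels={self.n_channels} does not match "
                f"{len(self.channel_names)} channel names"
            )
        if not self.epoch_len <= self.trial_len:
            raise ConfigError(
                f"epoch_len={self.epoch_len} exceeds trial_len={self.trial_len}"
            )
        lo, hi = self.mi_window
        if not (0.0 <= lo < hi <= self.epoch_len):
            raise ConfigError(
                f"mi_window={self.mi_window} must lie within [0, epoch_len]"
            )
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ConfigError(f"erd_depth={self.erd_depth} outside [0, 1]")
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigError(
                f"class_balance={self.class_balance} outside (0, 1)"
            )
        if self.fs < 2.0 * self.beta_band[1]:
            raise ConfigError(
                f"fs={self.fs} below Nyquist requirement "
                f"2×{self.beta_band[1]} Hz for the beta band"
            )
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigError(
                f"artifact_rate={self.artifact_rate} outside [0, 1]"
            )
        if self.n_trials < 1:
            raise ConfigError(f"n_trials={self.n_trials} must be >= 1")

    def replace(self, **kwargs) -> "SimConfig":
        d = asdict(self)
        d.update(kwargs)
        d["channel_names"] = tuple(d["channel_names"])
        for k in ("mi_window", "mu_band", "beta_band"):
            d[k] = tuple(d[k])
        return SimConfig(**d)


@dataclass
class RawRun:
    """One run of 16-channel EEG with event markers.

    ``data`` is channels × samples in µV; ``trial_onsets`` are sample
    indices of the trial cues; ``labels`` holds one of {"left",
    "right"} per trial. ``provenance`` records the generating config,
    the seed and the indices of artifact-injected trials (or the source
    file, for loaded runs).
    """

    data: np.ndarray
    fs: float
    trial_onsets: np.ndarray
    labels: np.ndarray
    channel_names: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.trial_onsets) != len(self.labels):
            raise DataError(
                f"{len(self.trial_onsets)} trial onsets but "
                f"{len(self.labels)} labels"
            )
        if np.any(np.diff(self.trial_onsets) <= 0):
            raise DataError("trial_onsets must be strictly increasing")
        if len(self.trial_onsets) and (
            self.trial_onsets[0] < 0 or self.trial_onsets[-1] >= self.data.shape[1]
        ):
            raise DataError("trial onsets fall outside the recording")

    @property
    def n_trials(self) -> int:
        return len(self.trial_onsets)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def erd_envelope(
    t,
    mi_window: tuple[float, float],
    erd_depth: float,
    ramp: float = 0.25,
):
    """Amplitude gain of the contralateral rhythm as a function of time.

    Returns 1 outside ``mi_window`` and ``sqrt(1 - erd_depth)`` inside,
    so the *variance* attenuation inside the window is exactly
    ``(1 - erd_depth)``. The gain descends/recovers over half-cosine
    ramps of width ``ramp`` seconds placed just inside the window
    edges; the boundary points themselves have gain 1. Accepts scalars
    or arrays; out-of-range times are simply "outside the window".
    """
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    lo, hi = mi_window
    g_in = np.sqrt(max(0.0, 1.0 - erd_depth))
    gain = np.ones_like(t)
    ramp = min(ramp, (hi - lo) / 2.0)
    inside = (t > lo) & (t < hi)
    gain[inside] = g_in
    if ramp > 0:
        fall = inside & (t < lo + ramp)
        rise = inside & (t > hi - ramp)
        # half-cosine from 1 down to g_in and back up
        gain[fall] = g_in + (1 - g_in) * 0.5 * (
            1 + np.cos(np.pi * (t[fall] - lo) / ramp)
        )
        gain[rise] = g_in + (1 - g_in) * 0.5 * (
            1 + np.cos(np.pi * (hi - t[rise]) / ramp)
        )
    return float(gain[0]) if scalar else gain


def _one_over_f_noise(
    rng: np.random.Generator, n_rows: int, n_samples: int,
    fs: float, exponent: float, std: float,
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit-free rows
    rescaled to the requested standard deviation."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_rows, freqs.size))
        + 1j * rng.standard_normal((n_rows, freqs.size))
    ) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x *= std / x.std(axis=1, keepdims=True)
    return x


def _band_limited_noise(
    rng: np.random.Generator, n_rows: int, n_samples: int,
    fs: float, band: tuple[float, float], std: float,
) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal((n_rows, n_samples)), axis=1)
    x *= std / x.std(axis=1, keepdims=True)
    return np.ascontiguousarray(x)


def simulate_run(config: SimConfig) -> RawRun:
    """Generate one run of synthetic motor-imagery EEG.

    The left-hemisphere (C3) and right-hemisphere (C4) rhythm sources
    run through the whole recording; within each trial, the source
    contralateral to the cued hand (C3 for right-hand trials, C4 for
    left-hand trials) is amplitude-modulated by :func:`erd_envelope`.
    Identical config (including seed) gives a bit-identical run.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    trial_samples = round(config.trial_len * fs)
    n = config.n_trials
    n_samples = n * trial_samples
    names = list(config.channel_names)

    # balanced, seeded class sequence
    n_left = int(round(config.class_balance * n))
    labels = np.array([LEFT] * n_left + [RIGHT] * (n - n_left), dtype=object)
    labels = labels[rng.permutation(n)]
    onsets = np.arange(n, dtype=np.int64) * trial_samples

    data = _one_over_f_noise(
        rng, len(names), n_samples, fs, config.noise_exponent,
        config.background_std,
    )

    # per-hemisphere modulation gains over the whole timeline
    t_rel = np.arange(trial_samples) / fs
    env = erd_envelope(t_rel, config.mi_window, config.erd_depth, config.erd_ramp)
    gain = {src: np.ones(n_samples) for src in ("C3", "C4")}
    for i, lab in enumerate(labels):
        contra = "C3" if lab == RIGHT else "C4"
        sl = slice(i * trial_samples, (i + 1) * trial_samples)
        gain[contra][sl] = env

    for src in ("C3", "C4"):
        weights = np.zeros(len(names))
        weights[names.index(src)] = 1.0
        for nb in _NEIGHBOURS[src]:
            weights[names.index(nb)] = 0.5
        mu = _band_limited_noise(rng, 1, n_samples, fs, config.mu_band,
                                 config.mu_amp)[0]
        beta = _band_limited_noise(rng, 1, n_samples, fs, config.beta_band,
                                   config.beta_amp)[0]
        data += np.outer(weights, (mu + beta) * gain[src])

    if config.line_amp > 0:
        t_abs = np.arange(n_samples) / fs
        phase = rng.uniform(0, 2 * np.pi)
        data += config.line_amp * np.sin(2 * np.pi * 50.0 * t_abs + phase)

    artifact_trials: list[int] = []
    n_art = int(round(config.artifact_rate * n))
    if n_art:
        artifact_trials = sorted(rng.choice(n, size=n_art, replace=False).tolist())
        burst = round(0.5 * fs)
        chan_sd = data.std(axis=1)
        for i in artifact_trials:
            chans = rng.choice(len(names), size=2, replace=False)
            start = i * trial_samples + rng.integers(
                0, max(1, round((config.epoch_len - 0.5) * fs))
            )
            for c in chans:
                data[c, start:start + burst] += 10.0 * chan_sd[c]

    prov = {
        "config": _config_to_jsonable(config),
        "seed": config.seed,
        "artifact_trials": artifact_trials,
    }
    return RawRun(data, fs, onsets, labels, tuple(names), prov)


# ---------------------------------------------------------------------------
# run I/O: CSV (samples × channels) + JSON sidecar


def _config_to_jsonable(config: SimConfig) -> dict:
    d = asdict(config)
    d["channel_names"] = list(d["channel_names"])
    for k in ("mi_window", "mu_band", "beta_band"):
        d[k] = list(d[k])
    return d


def save_run(run: RawRun, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (samples × channels, 9 significant digits)
    and ``<prefix>.json`` (fs, onsets, labels, provenance)."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    buf = io.StringIO()
    buf.write(",".join(run.channel_names) + "\n")
    np.savetxt(buf, run.data.T, fmt="%.9g", delimiter=",")
    csv_path.write_text(buf.getvalue())
    meta = {
        "fs": run.fs,
        "trial_onsets": run.trial_onsets.tolist(),
        "labels": list(run.labels),
        "channel_names": list(run.channel_names),
        "provenance": run.provenance,
    }
    json_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return csv_path, json_path


def load_run(prefix: str | Path) -> RawRun:
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    if not csv_path.exists():
        raise FileNotFoundError(f"run CSV not found: {csv_path}")
    if not json_path.exists():
        raise FileNotFoundError(f"run sidecar not found: {json_path}")
    meta = json.loads(json_path.read_text())
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1).T
    if data.ndim == 1:
        data = data[None, :]
    return RawRun(
        data=data,
        fs=meta["fs"],
        trial_onsets=np.asarray(meta["trial_onsets"], dtype=np.int64),
        labels=np.asarray(meta["labels"], dtype=object),
        channel_names=tuple(meta["channel_names"]),
        provenance=meta.get("provenance", {}),
    )
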