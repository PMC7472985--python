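"""Broadband conditioning, epoching, and artifact rejection.

The conditioning chain mirrors standard motor-imagery practice: a
zero-phase 0.5–30 Hz band-pass on the continuous recording, an optional
50 Hz notch, 8 s epochs cut at each trial cue, an 8–30 Hz narrow-band
pass per epoch (the mu/beta range CSP operates on), and a robust
amplitude-based trial rejection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import DataError, ParameterError
from .simulate import RawRun

LEFT, RIGHT = "left", "right"


@dataclass
class EpochSet:
    """Trialized EEG: trials × channels × samples plus labels.

    ``kept_mask`` marks trials that survived artifact rejection; all
    stages downstream should work on :meth:`kept` trials. ``band`` is
    the last band-pass applied (Hz), None if only broadband filtered.
    """

    epochs: np.ndarray
    labels: np.ndarray
    fs: float
    kept_mask: np.ndarray = None
    band: tuple[float, float] | None = None
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.kept_mask is None:
            self.kept_mask = np.ones(len(self.labels), dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.epochs.ndim != 3:
            raise DataError("epochs must be trials × channels × samples")
        if len(self.labels) != self.epochs.shape[0]:
            raise DataError("label count does not match trial count")
        if len(self.kept_mask) != self.epochs.shape[0]:
            raise DataError("kept_mask length does not match trial count")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def kept(self) -> tuple[np.ndarray, np.ndarray]:
        """(epochs, labels) restricted to retained trials."""
        return self.epochs[self.kept_mask], self.labels[self.kept_mask]

    def class_counts(self, kept_only: bool = True) -> dict[str, int]:
        labels = self.labels[self.kept_mask] if kept_only else self.labels
        return {c: int(np.sum(labels == c)) for c in (LEFT, RIGHT)}


def _bandpass_sos(low: float, high: float, fs: float, order: int = 4):
    if not 0.0 < low < high < fs / 2.0:
        raise ParameterError(
            f"band [{low}, {high}] Hz invalid for fs={fs} (need 0 < low < "
            f"high < Nyquist {fs / 2})"
        )
    return signal.butter(order, (low, high), btype="bandpass", fs=fs,
                         output="sos")


def broadband_filter(run: RawRun, low: float = 0.5, high: float = 30.0,
                     order: int = 4) -> RawRun:
    """Zero-phase Butterworth band-pass of the continuous recording."""
    sos = _bandpass_sos(low, high, run.fs, order)
    data = signal.sosfiltfilt(sos, run.data, axis=1)
    prov = dict(run.provenance)
    prov.setdefault("filters", []).append({"type": "bandpass",
                                           "band": [low, high]})
    return RawRun(data, run.fs, run.trial_onsets.copy(), run.labels.copy(),
                  run.channel_names, prov)


def notch_filter(run: RawRun, f0: float = 50.0, q: float = 35.0) -> RawRun:
    """Zero-phase IIR notch at the line frequency."""
    if not 0.0 < f0 < run.fs / 2.0:
        raise ParameterError(
            f"notch frequency {f0} Hz outside (0, Nyquist {run.fs / 2})"
        )
    b, a = signal.iirnotch(f0, q, fs=run.fs)
    data = signal.filtfilt(b, a, run.data, axis=1)
    prov = dict(run.provenance)
    prov.setdefault("filters", []).append({"type": "notch", "f0": f0})
    return RawRun(data, run.fs, run.trial_onsets.copy(), run.labels.copy(),
                  run.channel_names, prov)


def epoch_run(run: RawRun, epoch_len: float = 8.0) -> EpochSet:
    """Cut one fixed-length epoch per trial, starting at the cue."""
    n_samp = round(epoch_len * run.fs)
    n_total = run.data.shape[1]
    bad = [int(i) for i, on in enumerate(run.trial_onsets)
           if on + n_samp > n_total]
    if bad:
        raise DataError(
            f"epoch of {epoch_len} s does not fit the recording for "
            f"trial(s) {bad}"
        )
    if run.n_trials == 0:
        epochs = np.empty((0, run.n_channels, n_samp))
        warnings.warn("epoching a run with zero trials", stacklevel=2)
    else:
        idx = run.trial_onsets[:, None] + np.arange(n_samp)[None, :]
        epochs = run.data[:, idx].transpose(1, 0, 2)
    return EpochSet(epochs, run.labels.copy(), run.fs,
                    channel_names=run.channel_names)


def narrowband_filter(epochs: EpochSet, low: float = 8.0, high: float = 30.0,
                      order: int = 4) -> EpochSet:
    """Zero-phase band-pass applied per epoch; the band is recorded."""
    sos = _bandpass_sos(low, high, epochs.fs, order)
    if epochs.n_trials:
        data = signal.sosfiltfilt(sos, epochs.epochs, axis=2)
    else:
        data = epochs.epochs.copy()
    return replace(epochs, epochs=data, labels=epochs.labels.copy(),
                   kept_mask=epochs.kept_mask.copy(), band=(low, high))


def reject_artifacts(epochs: EpochSet, z_threshold: float = 5.0,
                     quantile: float = 0.95) -> EpochSet:
    """Flag trials with outlying sustained amplitude on any channel.

    For every channel, the per-trial sustained absolute amplitude (the
    ``quantile`` of \\|x\\| over the epoch — far more stable across
    trials than the raw maximum, yet driven to the artifact level by
    any burst longer than a few percent of the epoch) is scored
    against the median and MAD (scaled to be consistent with the SD of
    a normal distribution) of that channel's values across trials; a
    trial whose score exceeds ``z_threshold`` on any channel is
    dropped. Best applied to broadband epochs, before the 8–30 Hz
    narrow-band filter attenuates low-frequency artifact energy. At
    least two trials per class are always retained — if rejection
    would leave fewer, the least-extreme flagged trials of that class
    are reinstated with a warning.
    """
    counts = epochs.class_counts(kept_only=False)
    for cls, c in counts.items():
        if c < 2:
            raise DataError(
                f"need at least 2 trials per class before rejection; "
                f"class '{cls}' has {c}"
            )
    peaks = np.quantile(np.abs(epochs.epochs), quantile, axis=2)
    med = np.median(peaks, axis=0)
    mad = 1.4826 * np.median(np.abs(peaks - med), axis=0)
    scale = np.maximum(mad, 1e-12 * np.maximum(np.abs(med), 1.0))
    z = (peaks - med) / scale
    worst = z.max(axis=1)
    kept = worst <= z_threshold

    labels = epochs.labels
    for cls in (LEFT, RIGHT):
        in_cls = labels == cls
        if kept[in_cls].sum() < 2:
            # reinstate the least-extreme rejected trials of this class
            order = np.argsort(worst)
            need = 2 - int(kept[in_cls].sum())
            for i in order:
                if need == 0:
                    break
                if in_cls[i] and not kept[i]:
                    kept[i] = True
                    need -= 1
            warnings.warn(
                f"artifact rejection relaxed to keep 2 '{cls}' trials",
                stacklevel=2,
            )
    return replace(epochs, epochs=epochs.epochs.copy(),
                   labels=labels.copy(), kept_mask=kept)


# ---------------------------------------------------------------------------
# serialization: compressed tensor + JSON metadata


def save_epochs(epochs: EpochSet, prefix) -> None:
    from pathlib import Path

    prefix = Path(prefix)
    np.savez_compressed(prefix.with_suffix(".npz"), epochs=epochs.epochs)
    meta = {
        "fs": epochs.fs,
        "labels": list(epochs.labels),
        "kept_mask": epochs.kept_mask.tolist(),
        "band": list(epochs.band) if epochs.band else None,
        "channel_names": list(epochs.channel_names),
    }
    prefix.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def load_epochs(prefix) -> EpochSet:
    from pathlib import Path

    prefix = Path(prefix)
    arr = np.load(prefix.with_suffix(".npz"))["epochs"]
    meta = json.loads(prefix.with_suffix(".meta.json").read_text())
    return EpochSet(
        arr, np.asarray(meta["labels"], dtype=object), meta["fs"],
        kept_mask=np.asarray(meta["kept_mask"], dtype=bool),
        band=tuple(meta["band"]) if meta["band"] else None,
        channel_names=tuple(meta["channel_names"]),
    )
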