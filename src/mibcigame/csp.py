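"""Common Spatial Patterns: 16 channels → 4 discriminative channels.

CSP finds spatial filters w maximizing the variance ratio between the
two imagery classes. With trial-averaged, trace-normalized class
covariances C_L and C_R it solves the generalized eigenproblem

    C_L w = λ (C_L + C_R) w,      λ = wᵀC_Lw / wᵀ(C_L + C_R)w ∈ [0, 1].

Large λ means the filter output is dominated by left-class variance,
small λ by right-class variance. The filter bank keeps the two most
extreme eigenvectors from each end of the spectrum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path

import numpy as np
from scipy import linalg

from .errors import DataError
from .preprocess import EpochSet, LEFT, RIGHT


@dataclass
class CSPModel:
    """Fitted spatial filter bank.

    ``filters`` rows are the selected spatial filters (n_filters ×
    n_channels); ``eigenvalues`` is the full variance-ratio spectrum
    sorted descending; ``selected_idx`` indexes the chosen extremes.
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    selected_idx: np.ndarray
    band: tuple[float, float] | None
    n_train: dict
    channel_names: tuple[str, ...]

    def to_json(self, path) -> None:
        payload = {
            "filters": self.filters.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "selected_idx": self.selected_idx.tolist(),
            "band": list(self.band) if self.band else None,
            "n_train": self.n_train,
            "channel_names": list(self.channel_names),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "CSPModel":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["filters"]), np.asarray(d["eigenvalues"]),
            np.asarray(d["selected_idx"]),
            tuple(d["band"]) if d["band"] else None,
            d["n_train"], tuple(d["channel_names"]),
        )


def class_covariances(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged, trace-normalized covariance per class.

    Per-trial trace normalization makes the estimate robust to trial-
    to-trial amplitude drift: every trial contributes equal total power.
    """
    X, labels = epochs.kept()
    covs = {}
    for cls in (LEFT, RIGHT):
        trials = X[labels == cls]
        if len(trials) < 2:
            raise DataError(
                f"CSP needs >= 2 kept trials per class; '{cls}' has "
                f"{len(trials)}"
            )
        acc = np.zeros((X.shape[1], X.shape[1]))
        for tr in trials:
            c = tr @ tr.T
            acc += c / np.trace(c)
        covs[cls] = acc / len(trials)
    return covs[LEFT], covs[RIGHT]


def fit_csp(epochs: EpochSet, n_filters: int = 4,
            reg: float | None = None) -> CSPModel:
    """Fit the CSP filter bank on the kept trials of a narrow-band
    EpochSet.

    ``reg`` is the diagonal loading added to the composite covariance;
    defaults to 1e-8 × trace/n_channels. Returns the ``n_filters // 2``
    most left-discriminative and most right-discriminative filters,
    each scaled so its largest-magnitude coefficient is positive.
    """
    if n_filters % 2 or n_filters < 2:
        raise DataError(f"n_filters must be a positive even count, got {n_filters}")
    c_l, c_r = class_covariances(epochs)
    comp = c_l + c_r
    n_ch = comp.shape[0]
    if n_filters > n_ch:
        raise DataError(f"cannot select {n_filters} filters from {n_ch} channels")
    eps = reg if reg is not None else 1e-8 * np.trace(comp) / n_ch
    comp = comp + eps * np.eye(n_ch)
    try:
        w, v = linalg.eigh(c_l, comp)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise DataError(
            "composite covariance is rank deficient; increase the "
            "diagonal-loading regularization (reg parameter)"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise DataError(
            "generalized eigensolution is not finite; the composite "
            "covariance is rank deficient — increase reg"
        )
    order = np.argsort(w)[::-1]
    eigenvalues = np.clip(w[order], 0.0, 1.0)
    vectors = v[:, order]
    half = n_filters // 2
    selected = np.concatenate(
        [np.arange(half), np.arange(n_ch - half, n_ch)]
    )
    filters = vectors[:, selected].T.copy()
    # deterministic sign: largest-magnitude coefficient positive
    for row in filters:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    counts = epochs.class_counts()
    return CSPModel(
        filters=filters,
        eigenvalues=eigenvalues,
        selected_idx=selected,
        band=epochs.band,
        n_train={LEFT: counts[LEFT], RIGHT: counts[RIGHT]},
        channel_names=epochs.channel_names,
    )


def apply_csp(model: CSPModel, epochs: EpochSet) -> EpochSet:
    """Project every epoch through the filter bank (→ virtual channels)."""
    expected = tuple(model.channel_names)
    found = tuple(epochs.channel_names)
    if epochs.n_channels != model.filters.shape[1] or (
        expected and found and expected != found
    ):
        raise DataError(
            f"channel mismatch: model expects {list(expected)}, "
            f"epochs provide {list(found)}"
        )
    data = np.einsum("fc,tcs->tfs", model.filters, epochs.epochs)
    virtual = tuple(f"CSP{i + 1}" for i in range(model.filters.shape[0]))
    return dc_replace(
        epochs, epochs=data, labels=epochs.labels.copy(),
        kept_mask=epochs.kept_mask.copy(), channel_names=virtual,
    )
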