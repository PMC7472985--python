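"""Log-variance features, LDA, and cross-validated accuracy curves.

Features: at each of 14 timepoints (1.5–8 s in 0.5 s steps) the
variance of each of the 4 spatially filtered channels over the trailing
1.5 s window is computed, the 4 variances are normalized to sum to one,
and the natural log is taken. A single two-class LDA is trained on the
pooled (trial, timepoint) samples; accuracy is assessed by stratified
10-fold cross-validation at the trial level and reported per class and
per timepoint, summarized as the maximum or mean over timepoints.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field

from sklearn.model_selection import StratifiedKFold

from .errors import DataError, ParameterError
from .preprocess import EpochSet, LEFT, RIGHT

CLASSES = (LEFT, RIGHT)


def timepoint_grid(epoch_len: float = 8.0, start: float = 1.5,
                   step: float = 0.5) -> np.ndarray:
    """Inclusive arithmetic grid of feature timepoints (seconds)."""
    if step <= 0:
        raise ParameterError(f"step must be positive, got {step}")
    if start > epoch_len:
        raise ParameterError(
            f"grid start {start} s exceeds epoch length {epoch_len} s"
        )
    n = int(np.floor((epoch_len - start) / step + 1e-9)) + 1
    return np.round(start + step * np.arange(n), 9)


@dataclass
class FeatureBlock:
    """Normalized log-variance features: trials × timepoints × 4."""

    values: np.ndarray
    timepoints: np.ndarray
    labels: np.ndarray
    window_len: float = 1.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.timepoints = np.asarray(self.timepoints, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        t, p, f = self.values.shape
        if p != len(self.timepoints) or t != len(self.labels):
            raise DataError("feature tensor shape does not match metadata")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (trial·timepoint) samples with repeated labels."""
        t, p, f = self.values.shape
        X = self.values.reshape(t * p, f)
        y = np.repeat(self.labels, p)
        return X, y


def extract_features(epochs: EpochSet, grid: np.ndarray | None = None,
                     window_len: float = 1.5,
                     var_floor: float = 1e-12) -> FeatureBlock:
    """Windowed, sum-normalized log-variance of the virtual channels.

    The variance window is trailing — it ends at the timepoint and is
    clipped at the epoch start, so the default grid start of 1.5 s is
    the first complete window.
    """
    if epochs.n_channels != 4:
        raise ParameterError(
            f"feature extraction expects 4 spatially filtered channels, "
            f"got {epochs.n_channels}"
        )
    X, labels = epochs.kept()
    n_samp = X.shape[2]
    epoch_len = n_samp / epochs.fs
    if grid is None:
        grid = timepoint_grid(epoch_len=epoch_len)
    grid = np.asarray(grid, dtype=np.float64)
    feats = np.empty((X.shape[0], len(grid), 4))
    for j, t in enumerate(grid):
        i1 = min(n_samp, round(t * epochs.fs))
        i0 = max(0, round((t - window_len) * epochs.fs))
        if i1 <= 0 or i0 >= n_samp or i1 <= i0:
            raise ParameterError(
                f"variance window [{t - window_len}, {t}] s lies outside "
                f"the epoch [0, {epoch_len}] s"
            )
        var = X[:, :, i0:i1].var(axis=2)
        var = np.maximum(var, var_floor)
        var /= var.sum(axis=1, keepdims=True)
        feats[:, j, :] = np.log(var)
    return FeatureBlock(feats, grid, labels, window_len)


@dataclass
class LDAModel:
    """Equal-prior two-class Fisher discriminant.

    Decision value d(x) = wᵀx + b; d > 0 predicts the second class of
    ``class_order``, d ≤ 0 the first (ties go to the first class).
    """

    weights: np.ndarray
    bias: float
    class_order: tuple[str, str] = CLASSES

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        first, second = self.class_order
        return np.where(self.decision(X) > 0, second, first).astype(object)


def train_lda(X, y=None, ridge: float = 1e-9) -> LDAModel:
    """Train pooled LDA: w = Σ⁻¹(μ_R − μ_L), bias at the class midpoint.

    Accepts a FeatureBlock (pooled over timepoints) or an (X, y) pair.
    Σ is the pooled within-class covariance; a diagonal loading of
    ``ridge`` × mean(diag Σ) guards against singularity.
    """
    if isinstance(X, FeatureBlock):
        X, y = X.pooled()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=object)
    groups = {}
    for cls in CLASSES:
        g = X[y == cls]
        if len(g) < 2:
            raise DataError(
                f"LDA needs >= 2 samples per class; '{cls}' has {len(g)}"
            )
        groups[cls] = g
    mu = {cls: g.mean(axis=0) for cls, g in groups.items()}
    n = sum(len(g) for g in groups.values())
    scatter = sum(
        (g - mu[cls]).T @ (g - mu[cls]) for cls, g in groups.items()
    )
    sigma = scatter / (n - 2)
    sigma = sigma + ridge * np.mean(np.diag(sigma)) * np.eye(sigma.shape[0])
    w = np.linalg.solve(sigma, mu[RIGHT] - mu[LEFT])
    b = -0.5 * float(w @ (mu[LEFT] + mu[RIGHT]))
    return LDAModel(weights=w, bias=b)


@dataclass
class AccuracyResult:
    """Cross-validated per-class, per-timepoint accuracy (percent)."""

    acc: np.ndarray                      # 2 × timepoints, %
    timepoints: np.ndarray
    classes: tuple[str, str] = CLASSES
    folds: int = 10
    per_fold: np.ndarray = field(default=None)  # folds × 2 × timepoints

    @property
    def summary_max(self) -> np.ndarray:
        return self.acc.max(axis=1)

    @property
    def summary_mean(self) -> np.ndarray:
        return self.acc.mean(axis=1)

    def summarize(self, mode: str) -> np.ndarray:
        return summarize_accuracy(self, mode)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.acc, index=list(self.classes),
                            columns=np.round(self.timepoints, 3))


def summarize_accuracy(result: AccuracyResult, mode: str) -> np.ndarray:
    """Per-class scalar summary of the accuracy curve."""
    if mode == "max":
        return result.summary_max
    if mode == "mean":
        return result.summary_mean
    raise ParameterError(f"unknown summary mode '{mode}' (use 'max' or 'mean')")


def crossval_accuracy(features: FeatureBlock, k: int = 10,
                      seed: int | None = None,
                      per_timepoint: bool = False) -> AccuracyResult:
    """Stratified k-fold CV at the trial level.

    All timepoints of a trial stay in one fold. Per fold, LDA is
    trained on the pooled (trial, timepoint) samples of the training
    trials (or one LDA per timepoint when ``per_timepoint``), then each
    held-out trial is classified at every timepoint; accuracies are
    averaged over folds per class and timepoint.
    """
    labels = features.labels
    counts = {cls: int(np.sum(labels == cls)) for cls in CLASSES}
    if min(counts.values()) < k:
        raise ParameterError(
            f"k={k} folds exceed the smallest class size "
            f"{min(counts.values())} (counts: {counts})"
        )
    n_tp = len(features.timepoints)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_str = labels.astype(str)
    per_fold = np.full((k, 2, n_tp), np.nan)
    for f, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(len(labels)), y_str)):
        vals_tr = features.values[tr_idx]
        y_tr = labels[tr_idx]
        if per_timepoint:
            models = [
                train_lda(vals_tr[:, j, :], y_tr) for j in range(n_tp)
            ]
        else:
            pooled_X = vals_tr.reshape(-1, vals_tr.shape[2])
            pooled_y = np.repeat(y_tr, n_tp)
            models = [train_lda(pooled_X, pooled_y)] * n_tp
        y_te = labels[te_idx]
        for j in range(n_tp):
            pred = models[j].predict(features.values[te_idx, j, :])
            for c, cls in enumerate(CLASSES):
                sel = y_te == cls
                per_fold[f, c, j] = 100.0 * np.mean(pred[sel] == cls)
    acc = per_fold.mean(axis=0)
    return AccuracyResult(acc=acc, timepoints=features.timepoints,
                          folds=k, per_fold=per_fold)
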