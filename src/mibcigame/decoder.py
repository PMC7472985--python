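"""Model/results interface over the full decoding chain.

``MotorImageryDecoder`` is built from a raw run (or an already
narrow-band EpochSet) and ``fit()`` returns ``DecoderResults`` holding
the fitted CSP bank, the pooled LDA, the cross-validated accuracy
curves, and a ``summary()`` table. Everything it does is delegated to
the stage functions in :mod:`preprocess`, :mod:`csp` and
:mod:`classify`, which remain usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classify, csp, preprocess
from .classify import AccuracyResult, FeatureBlock, LDAModel, CLASSES
from .csp import CSPModel
from .preprocess import EpochSet
from .simulate import RawRun


class MotorImageryDecoder:
    """CSP + LDA motor-imagery decoder for one run (or pooled runs).

    Parameters
    ----------
    epochs
        Narrow-band filtered, artifact-rejected EpochSet (8–30 Hz at
        defaults) with 16 channels.
    n_csp
        Number of spatial filters (2 from each end of the spectrum).
    grid
        Feature timepoints in seconds; defaults to 1.5–8 s in 0.5 s
        steps (14 points).
    window_len
        Trailing variance window in seconds.
    """

    def __init__(self, epochs: EpochSet, n_csp: int = 4,
                 grid: np.ndarray | None = None, window_len: float = 1.5):
        self.epochs = epochs
        self.n_csp = n_csp
        self.grid = (np.asarray(grid, dtype=float) if grid is not None
                     else classify.timepoint_grid())
        self.window_len = window_len

    @classmethod
    def from_run(cls, run: RawRun, broadband: tuple[float, float] = (0.5, 30.0),
                 notch: float | None = 50.0,
                 band: tuple[float, float] = (8.0, 30.0),
                 epoch_len: float = 8.0, z_threshold: float = 5.0,
                 **kwargs) -> "MotorImageryDecoder":
        """Run the full conditioning chain, then build the decoder."""
        run = preprocess.broadband_filter(run, *broadband)
        if notch is not None:
            run = preprocess.notch_filter(run, notch)
        ep = preprocess.epoch_run(run, epoch_len)
        # rejection sees broadband amplitudes; the narrow band would
        # hide low-frequency artifact energy
        ep = preprocess.reject_artifacts(ep, z_threshold)
        ep = preprocess.narrowband_filter(ep, *band)
        return cls(ep, **kwargs)

    @classmethod
    def from_epochsets(cls, parts: list[EpochSet], **kwargs
                       ) -> "MotorImageryDecoder":
        """Pool several runs' epochs (e.g. calibration + training 1)."""
        ep0 = parts[0]
        merged = EpochSet(
            np.concatenate([p.epochs for p in parts], axis=0),
            np.concatenate([p.labels for p in parts]),
            ep0.fs,
            kept_mask=np.concatenate([p.kept_mask for p in parts]),
            band=ep0.band,
            channel_names=ep0.channel_names,
        )
        return cls(merged, **kwargs)

    def fit(self, folds: int = 10, seed: int | None = None,
            per_timepoint: bool = False,
            refit_csp_per_fold: bool = True) -> "DecoderResults":
        """Fit the deployable CSP + LDA on all kept trials and estimate
        accuracy by stratified cross-validation at the trial level.

        By default the whole chain — CSP bank included — is refit on
        each fold's training trials, so held-out trials never influence
        the spatial filters (a CSP fitted on all trials inflates
        accuracy above chance even for exchangeable classes). Setting
        ``refit_csp_per_fold=False`` reproduces the cheaper variant
        that fixes the full-data CSP and only refits the LDA per fold.
        """
        model = csp.fit_csp(self.epochs, n_filters=self.n_csp)
        virtual = csp.apply_csp(model, self.epochs)
        features = classify.extract_features(virtual, self.grid,
                                             self.window_len)
        lda = classify.train_lda(features)
        if refit_csp_per_fold:
            accuracy = self._crossval_chain(folds, seed, per_timepoint)
        else:
            accuracy = classify.crossval_accuracy(
                features, k=folds, seed=seed, per_timepoint=per_timepoint)
        return DecoderResults(decoder=self, csp_model=model, lda_model=lda,
                              features=features, accuracy=accuracy,
                              folds=folds, seed=seed)

    def _crossval_chain(self, folds: int, seed: int | None,
                        per_timepoint: bool) -> AccuracyResult:
        """Stratified trial-level CV refitting CSP + LDA per fold."""
        from sklearn.model_selection import StratifiedKFold

        from .errors import ParameterError

        X, labels = self.epochs.kept()
        counts = {c: int(np.sum(labels == c)) for c in CLASSES}
        if min(counts.values()) < folds:
            raise ParameterError(
                f"k={folds} folds exceed the smallest class size "
                f"{min(counts.values())} (counts: {counts})"
            )
        n_tp = len(self.grid)
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed)
        per_fold = np.full((folds, 2, n_tp), np.nan)
        for f, (tr, te) in enumerate(
                skf.split(np.zeros(len(labels)), labels.astype(str))):
            fold_train = EpochSet(X[tr], labels[tr], self.epochs.fs,
                                  band=self.epochs.band,
                                  channel_names=self.epochs.channel_names)
            model = csp.fit_csp(fold_train, n_filters=self.n_csp)
            feats_tr = classify.extract_features(
                csp.apply_csp(model, fold_train), self.grid,
                self.window_len)
            fold_test = EpochSet(X[te], labels[te], self.epochs.fs,
                                 band=self.epochs.band,
                                 channel_names=self.epochs.channel_names)
            feats_te = classify.extract_features(
                csp.apply_csp(model, fold_test), self.grid,
                self.window_len)
            if per_timepoint:
                models = [classify.train_lda(feats_tr.values[:, j, :],
                                             feats_tr.labels)
                          for j in range(n_tp)]
            else:
                models = [classify.train_lda(feats_tr)] * n_tp
            for j in range(n_tp):
                pred = models[j].predict(feats_te.values[:, j, :])
                for c, cls in enumerate(CLASSES):
                    sel = feats_te.labels == cls
                    per_fold[f, c, j] = 100.0 * np.mean(pred[sel] == cls)
        return AccuracyResult(acc=per_fold.mean(axis=0),
                              timepoints=np.asarray(self.grid),
                              folds=folds, per_fold=per_fold)


@dataclass
class DecoderResults:
    """Fitted decoder plus its cross-validated accuracy curves."""

    decoder: MotorImageryDecoder
    csp_model: CSPModel
    lda_model: LDAModel
    features: FeatureBlock
    accuracy: AccuracyResult
    folds: int = 10
    seed: int | None = None

    @property
    def summary_max(self) -> np.ndarray:
        return self.accuracy.summary_max

    @property
    def summary_mean(self) -> np.ndarray:
        return self.accuracy.summary_mean

    def summary(self) -> str:
        """Text table: per-class accuracy curve and its summaries."""
        lines = [
            "Motor-imagery decoder (CSP + LDA, "
            f"{self.folds}-fold CV, {self.features.n_trials} trials)",
            "",
            "timepoint[s] " + " ".join(
                f"{t:6.1f}" for t in self.accuracy.timepoints),
        ]
        for c, cls in enumerate(self.accuracy.classes):
            lines.append(
                f"{cls:>11}: " + " ".join(
                    f"{a:6.1f}" for a in self.accuracy.acc[c])
            )
        mx, mn = self.summary_max, self.summary_mean
        lines.append("")
        for c, cls in enumerate(self.accuracy.classes):
            lines.append(
                f"{cls:>11}: max accuracy {mx[c]:5.1f} %   "
                f"mean accuracy {mn[c]:5.1f} %"
            )
        return "\n".join(lines)

    def classify_epochs(self, epochs: EpochSet) -> np.ndarray:
        """Per-trial, per-timepoint predicted labels for new epochs."""
        virtual = csp.apply_csp(self.csp_model, epochs)
        features = classify.extract_features(
            virtual, self.decoder.grid, self.decoder.window_len)
        n_tr, n_tp, _ = features.values.shape
        preds = np.empty((n_tr, n_tp), dtype=object)
        for j in range(n_tp):
            preds[:, j] = self.lda_model.predict(features.values[:, j, :])
        return preds

    def correctness_events(self, epochs: EpochSet) -> list[np.ndarray]:
        """Boolean correctness stream per trial (one event per
        timepoint), the input the game's trial resolution consumes."""
        preds = self.classify_epochs(epochs)
        _, labels = epochs.kept()
        return [preds[i] == labels[i] for i in range(len(labels))]

    def plot_accuracy(self, ax=None):
        """Accuracy curves per class over the timepoint grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c, cls in enumerate(self.accuracy.classes):
            ax.plot(self.accuracy.timepoints, self.accuracy.acc[c],
                    marker="o", label=cls)
        ax.axhline(50, color="grey", ls=":", lw=1)
        ax.set_xlabel("timepoint [s]")
        ax.set_ylabel("CV accuracy [%]")
        ax.set_ylim(0, 100)
        ax.legend()
        return ax
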