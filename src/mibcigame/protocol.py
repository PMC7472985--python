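"""Two-session, three-run experimental protocol on synthetic subjects.

Each subject performs two sessions of three 80-trial runs: Calibration
(C), Training 1 (T1) and Training 2 (T2). Online feedback in T1 comes
from the classifier fitted on C; in T2 from a classifier refitted on
the pooled C + T1 trials; calibration feedback is always positive.
Sessions are independent — session 2 never reuses session-1
classifiers. Offline, every run is scored by the 10-fold
cross-validated CSP + LDA chain on its own trials, and the per-run
summaries are laid out in the five reported columns (C-S1, T1_S1,
T2_S1, T1_S2, T2_S2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess
from .classify import CLASSES, AccuracyResult
from .decoder import DecoderResults, MotorImageryDecoder
from .errors import ConfigError
from .game import GameState, play_session
from .simulate import SimConfig, simulate_run

FEEDBACK_MODES = ("standard-avatar", "game-no-feedback",
                  "game-intermittent", "game-constant")

#: Columns of the reported per-subject accuracy table (C-S2 is a
#: calibration run of session 2 and is not part of the reported layout).
REPORT_COLUMNS = ("C-S1", "T1_S1", "T2_S1", "T1_S2", "T2_S2")


@dataclass(frozen=True)
class RunSpec:
    name: str
    session: int
    stage: str                 # "C", "T1" or "T2"
    feedback: str
    classifier_source: str     # "self", "calibration" or "pooled"


@dataclass(frozen=True)
class SessionPlan:
    """Ordered run specifications for the two sessions."""

    runs: tuple[RunSpec, ...]

    def __post_init__(self) -> None:
        for session in sorted({r.session for r in self.runs}):
            stages = [r.stage for r in self.runs if r.session == session]
            if stages != ["C", "T1", "T2"]:
                raise ConfigError(
                    f"session {session} must run C, T1, T2 in order; "
                    f"got {stages}"
                )
        for r in self.runs:
            if r.feedback not in FEEDBACK_MODES:
                raise ConfigError(f"unknown feedback mode '{r.feedback}'")
            expected = {"C": "self", "T1": "calibration", "T2": "pooled"}
            if r.classifier_source != expected[r.stage]:
                raise ConfigError(
                    f"run {r.name}: stage {r.stage} must use the "
                    f"'{expected[r.stage]}' classifier, "
                    f"got '{r.classifier_source}'"
                )

    def __iter__(self):
        return iter(self.runs)


def default_plan() -> SessionPlan:
    """The study's feedback schedule: session 1 introduces the game in
    T2 (no score panel); session 2 is fully gamified with intermittent
    then constant score feedback."""
    return SessionPlan((
        RunSpec("C-S1", 1, "C", "standard-avatar", "self"),
        RunSpec("T1-S1", 1, "T1", "standard-avatar", "calibration"),
        RunSpec("T2-S1", 1, "T2", "game-no-feedback", "pooled"),
        RunSpec("C-S2", 2, "C", "game-no-feedback", "self"),
        RunSpec("T1-S2", 2, "T1", "game-intermittent", "calibration"),
        RunSpec("T2-S2", 2, "T2", "game-constant", "pooled"),
    ))


_PANEL = {"standard-avatar": "none", "game-no-feedback": "none",
          "game-intermittent": "intermittent", "game-constant": "constant"}


@dataclass
class SubjectResult:
    """Per-run scores of one synthetic subject."""

    subject: int
    table: pd.DataFrame                      # (mode, class) × report columns
    accuracies: dict[str, AccuracyResult]
    games: dict[str, GameState]
    seed: int

    def cell(self, run: str, mode: str) -> float:
        """Class-averaged summary accuracy of one run (ANOVA cell)."""
        return float(self.table.loc[mode, run].mean())


def _condition(run, notch: bool):
    run = preprocess.broadband_filter(run)
    if notch:
        run = preprocess.notch_filter(run)
    ep = preprocess.epoch_run(run)
    ep = preprocess.reject_artifacts(ep)
    return preprocess.narrowband_filter(ep)


def run_subject(config: SimConfig, plan: SessionPlan | None = None,
                seed: int | None = None,
                erd_offsets: dict[str, float] | None = None,
                folds: int = 10, play_games: bool = True) -> SubjectResult:
    """Simulate and score one subject's full protocol.

    ``erd_offsets`` optionally shifts ``erd_depth`` per run (clipped to
    [0, 1]) to inject or suppress condition effects; the default (none)
    encodes the study's null: feedback mode does not change the
    underlying imagery signal.
    """
    plan = plan or default_plan()
    if seed is None:
        seed = config.seed
    run_seeds = (np.random.SeedSequence(seed).generate_state(len(plan.runs))
                 % (2 ** 31)).astype(int)
    erd_offsets = erd_offsets or {}

    epochsets: dict[str, preprocess.EpochSet] = {}
    accuracies: dict[str, AccuracyResult] = {}
    games: dict[str, GameState] = {}
    session_fits: dict[tuple[int, str], DecoderResults] = {}

    for spec, rseed in zip(plan.runs, run_seeds):
        depth = float(np.clip(
            config.erd_depth + erd_offsets.get(spec.name, 0.0), 0.0, 1.0))
        cfg = config.replace(seed=int(rseed), erd_depth=depth)
        try:
            raw = simulate_run(cfg)
            ep = _condition(raw, notch=cfg.line_amp > 0)
            epochsets[spec.name] = ep
            res = MotorImageryDecoder(ep).fit(folds=folds, seed=int(rseed))
            accuracies[spec.name] = res.accuracy
            if play_games:
                if spec.stage == "C":
                    session_fits[(spec.session, "C")] = res
                elif spec.stage == "T1":
                    # pooled classifier drives online feedback in T2
                    c_name = next(
                        r.name for r in plan.runs
                        if r.session == spec.session and r.stage == "C")
                    pooled = MotorImageryDecoder.from_epochsets(
                        [epochsets[c_name], ep]).fit(folds=folds,
                                                     seed=int(rseed))
                    session_fits[(spec.session, "pooled")] = pooled
        except Exception as exc:
            raise type(exc)(f"[run {spec.name}] {exc}") from exc

        if play_games and spec.feedback != "standard-avatar":
            if spec.stage == "C":
                # calibration feedback is always positive
                n_kept = int(epochsets[spec.name].kept_mask.sum())
                n_tp = len(MotorImageryDecoder(ep).grid)
                streams = [np.ones(n_tp, bool)] * n_kept
            else:
                source = "C" if spec.stage == "T1" else "pooled"
                online = session_fits[(spec.session, source)]
                streams = online.correctness_events(epochsets[spec.name])
            games[spec.name] = play_session(
                streams, panel_mode=_PANEL[spec.feedback])

    rows = []
    index = []
    for mode in ("max", "mean"):
        for c, cls in enumerate(CLASSES):
            index.append((mode, cls))
            rows.append([
                accuracies[name].summarize(mode)[c]
                for name in ("C-S1", "T1-S1", "T2-S1", "T1-S2", "T2-S2")
            ])
    table = pd.DataFrame(
        rows, columns=list(REPORT_COLUMNS),
        index=pd.MultiIndex.from_tuples(index, names=["summary", "class"]),
    )
    return SubjectResult(subject=seed, table=table, accuracies=accuracies,
                         games=games, seed=seed)


@dataclass
class StudyResult:
    """A cohort of synthetic subjects run through the protocol."""

    subjects: list[SubjectResult]
    config: SimConfig
    seed: int

    def long_table(self) -> pd.DataFrame:
        """(subject, run, summary, class, accuracy) long format."""
        frames = []
        for s in self.subjects:
            t = s.table.stack().rename("accuracy").reset_index()
            t.columns = ["summary", "class", "run", "accuracy"]
            t.insert(0, "subject", s.subject)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def anova_matrix(self, mode: str = "max",
                     cells: tuple[str, ...] = ("T1_S1", "T2_S1", "T1_S2",
                                               "T2_S2")) -> np.ndarray:
        """Subjects × cells matrix of class-averaged accuracies, the
        input of the repeated-measures ANOVA. Cell selection is
        configurable (which runs enter the comparison)."""
        out = np.empty((len(self.subjects), len(cells)))
        for i, s in enumerate(self.subjects):
            for j, cell in enumerate(cells):
                out[i, j] = s.table.loc[mode, cell].mean()
        return out

    def aggregate(self) -> pd.DataFrame:
        """Mean (SD) of class-averaged accuracy per run and summary."""
        rows = {}
        for mode in ("max", "mean"):
            vals = np.array([
                [s.table.loc[mode, col].mean() for col in REPORT_COLUMNS]
                for s in self.subjects
            ])
            rows[(mode, "mean")] = vals.mean(axis=0)
            rows[(mode, "sd")] = vals.std(axis=0, ddof=1) if len(
                self.subjects) > 1 else np.full(vals.shape[1], np.nan)
        return pd.DataFrame(rows, index=list(REPORT_COLUMNS)).T


def run_study(n_subjects: int, config: SimConfig | None = None,
              seed: int = 0, plan: SessionPlan | None = None,
              erd_offsets: dict[str, float] | None = None,
              folds: int = 10, play_games: bool = False) -> StudyResult:
    """Run the full protocol for a cohort of synthetic subjects."""
    config = config or SimConfig()
    subject_seeds = (np.random.SeedSequence(seed)
                     .generate_state(n_subjects) % (2 ** 31)).astype(int)
    subjects = [
        run_subject(config, plan=plan, seed=int(s),
                    erd_offsets=erd_offsets, folds=folds,
                    play_games=play_games)
        for s in subject_seeds
    ]
    return StudyResult(subjects=subjects, config=config, seed=seed)
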