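"""Cheese/rat game: the deterministic scoring layer of the trials.

Each of the 80 exercises stakes one piece of cheese. During the
feedback sub-stage the classifier emits boolean correctness events; if
the trial contains a run of at least five consecutive correct events
the rat leaves empty-handed (the user "saves" the cheese), otherwise
the rat takes a piece. A score panel can be hidden, shown
intermittently, or shown constantly — it only affects presentation,
never scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import DataError, ParameterError, StateError

SAVED, TAKEN = "saved", "taken"
PANEL_MODES = ("none", "intermittent", "constant")

#: Consecutive correct events needed to save a piece of cheese.
RUN_LENGTH = 5


@dataclass(frozen=True)
class GameState:
    """Immutable snapshot of a session's game."""

    n_trials: int
    cheese: int
    trial_index: int = 0
    outcomes: tuple[str, ...] = ()
    panel_mode: str = "none"
    user_score: int = 0
    rat_score: int = 0


def init_game(n_trials: int = 80, panel_mode: str = "none") -> GameState:
    """One piece of cheese per exercise, scores at zero."""
    if n_trials < 1:
        raise ParameterError(f"n_trials must be >= 1, got {n_trials}")
    if panel_mode not in PANEL_MODES:
        raise ParameterError(
            f"panel_mode '{panel_mode}' not in {PANEL_MODES}"
        )
    return GameState(n_trials=n_trials, cheese=n_trials,
                     panel_mode=panel_mode)


def longest_true_run(events: Sequence[bool]) -> int:
    best = cur = 0
    for e in events:
        cur = cur + 1 if e else 0
        best = max(best, cur)
    return best


def resolve_trial(events: Sequence[bool], rule: str = "any_run",
                  run_length: int = RUN_LENGTH) -> str:
    """'saved' iff the event stream meets the correctness criterion.

    ``rule='any_run'`` (default): any run of ``run_length`` consecutive
    correct events anywhere in the stream saves the cheese.
    ``rule='suffix'``: the last ``run_length`` events must all be
    correct (the run must still be alive when the arm lowers).
    """
    events = [bool(e) for e in events]
    if not events:
        raise DataError("trial event stream is empty")
    if rule == "any_run":
        ok = longest_true_run(events) >= run_length
    elif rule == "suffix":
        ok = len(events) >= run_length and all(events[-run_length:])
    else:
        raise ParameterError(f"unknown rule '{rule}'")
    return SAVED if ok else TAKEN


def update_state(state: GameState, outcome: str) -> GameState:
    """Advance the game by one resolved trial."""
    if state.trial_index >= state.n_trials:
        raise StateError(
            f"all {state.n_trials} trials already resolved"
        )
    if outcome == SAVED:
        return replace(state, trial_index=state.trial_index + 1,
                       outcomes=state.outcomes + (SAVED,),
                       user_score=state.user_score + 1)
    if outcome == TAKEN:
        return replace(state, trial_index=state.trial_index + 1,
                       outcomes=state.outcomes + (TAKEN,),
                       cheese=state.cheese - 1,
                       rat_score=state.rat_score + 1)
    raise ParameterError(f"unknown outcome '{outcome}'")


def play_session(event_streams: Iterable[Sequence[bool]],
                 n_trials: int | None = None, panel_mode: str = "none",
                 rule: str = "any_run") -> GameState:
    """Resolve a full session of trials from their event streams."""
    streams = list(event_streams)
    state = init_game(n_trials if n_trials is not None else len(streams),
                      panel_mode)
    for events in streams:
        state = update_state(state, resolve_trial(events, rule=rule))
    return state


def write_game_log(path, streams: Iterable[Sequence[bool]],
                   panel_mode: str = "none", rule: str = "any_run") -> GameState:
    """Play a session and write a JSON-lines log (one trial per line)."""
    streams = list(streams)
    state = init_game(len(streams), panel_mode)
    with open(path, "w") as fh:
        for i, events in enumerate(streams):
            outcome = resolve_trial(events, rule=rule)
            state = update_state(state, outcome)
            fh.write(json.dumps({
                "trial": i, "events": [bool(e) for e in events],
                "outcome": outcome, "cheese": state.cheese,
            }) + "\n")
    return state
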