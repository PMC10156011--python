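"""Adaptive-staircase engine for 2IFC pitch-change detection.

Implements the transformed up-down procedure (Levitt's one-up, two-down
rule): the tracked level — here the magnitude of a pitch shift in cents —
gets harder (smaller) after two consecutive correct responses and easier
(larger) after any error. At equilibrium the rule converges on the level
answered correctly with probability sqrt(0.5) ≈ 0.707, the 70.7% point of
the psychometric function.

Defaults follow the calibration procedure this package reproduces: start
at 200 cents with a 40-cent step, halve the step after every two
reversals down to a 5-cent floor, stop after twelve reversals, and
estimate the threshold as the mean of the last six reversal levels.

A trial at which the level's direction of movement changes is a reversal;
the level *at* the turning point (the local extremum) is recorded. When a
reversal brings the accumulated count to a multiple of the halving
period, the step is halved before the next level move.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "StaircaseError",
    "NonConvergenceError",
    "StaircaseDivergenceWarning",
    "staircase_update",
    "staircase_threshold",
    "run_staircase",
    "staircase_log_to_csv",
    "replay_threshold",
]


class StaircaseError(RuntimeError):
    pass


class NonConvergenceError(StaircaseError):
    """Raised when a staircase fails to terminate within the trial cap."""


class StaircaseDivergenceWarning(UserWarning):
    """Emitted when a track drifts upward past its starting level —
    the signature of an observer at or near chance."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the one-up, two-down procedure."""

    initial_level_cents: float = 200.0
    initial_step_cents: float = 40.0
    min_step_cents: float = 5.0
    reversals_to_stop: int = 12
    reversals_to_average: int = 6
    halve_every_n_reversals: int = 2
    level_floor_cents: float = 1.0
    max_trials: int = 1000
    target_p: float = 0.5 ** 0.5  # ≈ 0.707, fixed by the 1-up-2-down rule

    def validate(self) -> None:
        if self.reversals_to_average > self.reversals_to_stop:
            raise ValueError("reversals_to_average must be <= reversals_to_stop")
        if self.min_step_cents > self.initial_step_cents:
            raise ValueError("min_step_cents must be <= initial_step_cents")
        if self.level_floor_cents <= 0:
            raise ValueError("level_floor_cents must be positive")

    def step_for_reversal_count(self, n_reversals: int) -> float:
        """Deterministic step schedule: halve after every
        ``halve_every_n_reversals`` accumulated reversals, floored."""
        halvings = n_reversals // self.halve_every_n_reversals
        return max(self.initial_step_cents / (2.0**halvings), self.min_step_cents)


@dataclass(frozen=True)
class StaircaseState:
    """Running state of one staircase track."""

    level_cents: float
    step_cents: float
    consecutive_correct: int = 0
    last_direction: str = "none"  # "up" | "down" | "none"
    reversal_levels: tuple[float, ...] = ()
    trial_log: tuple[tuple[float, bool], ...] = ()
    terminated: bool = False

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_levels)

    @property
    def n_trials(self) -> int:
        return len(self.trial_log)


def initial_state(config: StaircaseConfig) -> StaircaseState:
    config.validate()
    return StaircaseState(
        level_cents=config.initial_level_cents,
        step_cents=config.initial_step_cents,
    )


def staircase_update(
    state: StaircaseState, correct: bool, config: StaircaseConfig
) -> StaircaseState:
    """Advance the staircase by one trial outcome.

    One-up, two-down: an error moves the level up by the current step and
    resets the correct counter; a second consecutive correct moves it down
    and resets the counter; a first correct leaves the level unchanged.
    Direction changes append the turning level (the level at the current
    trial) to the reversal record; the step halves whenever the reversal
    count reaches a multiple of the halving period, before the next move.
    """
    if state.terminated:
        raise StaircaseError("staircase already terminated")
    log = state.trial_log + ((state.level_cents, bool(correct)),)

    if correct and state.consecutive_correct + 1 < 2:
        # first correct in a row: no movement
        return replace(state, consecutive_correct=1, trial_log=log)

    direction = "down" if correct else "up"
    reversal_levels = state.reversal_levels
    if state.last_direction != "none" and direction != state.last_direction:
        reversal_levels = reversal_levels + (state.level_cents,)

    step = config.step_for_reversal_count(len(reversal_levels))
    delta = -step if correct else step
    new_level = max(state.level_cents + delta, config.level_floor_cents)
    terminated = len(reversal_levels) >= config.reversals_to_stop
    return StaircaseState(
        level_cents=new_level,
        step_cents=step,
        consecutive_correct=0,
        last_direction=direction,
        reversal_levels=reversal_levels,
        trial_log=log,
        terminated=terminated,
    )


def staircase_threshold(state: StaircaseState, config: StaircaseConfig) -> float:
    """Threshold estimate: mean of the last ``reversals_to_average``
    reversal levels. Requires the full reversal count."""
    if state.n_reversals < config.reversals_to_stop:
        raise StaircaseError(
            f"need {config.reversals_to_stop} reversals, have {state.n_reversals}"
        )
    tail = state.reversal_levels[-config.reversals_to_average :]
    return float(np.mean(tail))


def run_staircase(
    observer: Callable[[float, np.random.Generator], bool],
    config: StaircaseConfig = StaircaseConfig(),
    seed: int | np.random.Generator = 0,
) -> tuple[float, StaircaseState]:
    """Run a simulated staircase to termination.

    ``observer(level_cents, rng) -> bool`` decides each trial. Returns the
    threshold (mean of the last six reversal levels) and the final state.

    Degenerate observers are diagnosed rather than looped on: a track
    pinned at the level floor for 30 consecutive trials (a near-perfect
    observer whose down-moves are clamped, so no further reversals can
    occur) terminates with the floor as its threshold, and a threshold at
    or above the starting level (an observer near chance, whose track
    drifts upward) emits :class:`StaircaseDivergenceWarning`. If the
    reversal criterion is still not reached within ``config.max_trials``
    trials, :class:`NonConvergenceError` is raised.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = initial_state(config)
    floor_streak = 0
    while not state.terminated:
        if state.n_trials >= config.max_trials:
            raise NonConvergenceError(
                f"staircase did not terminate within {config.max_trials} trials "
                f"({state.n_reversals} reversals reached)"
            )
        state = staircase_update(state, observer(state.level_cents, rng), config)
        if state.level_cents <= config.level_floor_cents:
            floor_streak += 1
            if floor_streak >= 30:
                warnings.warn(
                    "staircase pinned at the level floor; observer near ceiling",
                    StaircaseDivergenceWarning,
                )
                return config.level_floor_cents, replace(state, terminated=True)
        else:
            floor_streak = 0
    threshold = staircase_threshold(state, config)
    if threshold >= config.initial_level_cents:
        warnings.warn(
            f"staircase threshold {threshold:.0f} cents at or above the starting "
            f"level {config.initial_level_cents:.0f}; observer near chance",
            StaircaseDivergenceWarning,
        )
    return threshold, state


def replay_threshold(
    trial_log: tuple[tuple[float, bool], ...], config: StaircaseConfig
) -> float:
    """Recompute the threshold from a raw (level, correct) trial log.

    Replays the one-up-two-down bookkeeping from scratch; used as an
    independent check that live state updates match the recorded history.
    """
    state = initial_state(config)
    for _, correct in trial_log:
        state = staircase_update(state, correct, config)
    return staircase_threshold(state, config)


def staircase_log_to_csv(state: StaircaseState, config: StaircaseConfig, path) -> None:
    """Write the trial-by-trial log (trial, level_cents, correct, step_cents,
    is_reversal) as CSV."""
    import pandas as pd

    # recompute per-trial step and reversal flags by replaying the log
    rows = []
    st = initial_state(config)
    for i, (level, correct) in enumerate(state.trial_log):
        before = st.n_reversals
        st = staircase_update(st, correct, config)
        rows.append(
            {
                "trial": i + 1,
                "level_cents": level,
                "correct": int(correct),
                "step_cents": st.step_cents,
                "is_reversal": int(st.n_reversals > before),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
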