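"""Performance-contingent response-deadline controller.

The adaptive difficulty mechanism of the gamified condition is a one-way
staircase on the response window: after every run of ``streak_target``
consecutive correct responses the window allotted for a response shrinks by
``step_ms``; any commission or omission error resets the streak and leaves
the window unchanged (difficulty stagnates).  The window never increases and
never drops below ``floor_ms``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .enums import Outcome

__all__ = ["StaircaseConfig", "StaircaseState", "init_state", "update"]


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the descending response-window staircase.

    Parameters
    ----------
    start_window_ms
        Response window on the first test trial, in milliseconds.
    step_ms
        Amount the window shrinks after each completed correct streak.
    streak_target
        Number of consecutive correct responses required for one decrement.
    floor_ms
        Hard lower bound on the window; decrements clamp here.
    n_levels
        Number of hidden levels the test block is partitioned into
        (``streak_target`` trials per level).
    level_reset
        If True, the correct-streak counter is reset at hidden-level
        boundaries so a decrement can only be earned by a fully correct
        level block; if False (default) the streak rolls across levels.
    """

    start_window_ms: float = 8000.0
    step_ms: float = 500.0
    streak_target: int = 3
    floor_ms: float = 500.0
    n_levels: int = 14
    level_reset: bool = False

    def __post_init__(self) -> None:
        if self.start_window_ms <= 0:
            raise ValueError("start_window_ms must be positive")
        if self.step_ms < 0:
            raise ValueError("step_ms may not be negative")
        if self.streak_target < 1:
            raise ValueError("streak_target must be at least 1")
        if self.floor_ms <= 0:
            raise ValueError("floor_ms must be positive")
        if self.floor_ms > self.start_window_ms:
            raise ValueError(
                f"floor_ms ({self.floor_ms}) exceeds start_window_ms "
                f"({self.start_window_ms})"
            )
        if self.n_levels < 1:
            raise ValueError("n_levels must be at least 1")


@dataclass(frozen=True)
class StaircaseState:
    """Current window, correct streak, and number of decrements applied."""

    window_ms: float
    streak: int = 0
    decrements_applied: int = 0


def init_state(config: StaircaseConfig) -> StaircaseState:
    """Return the state before the first test trial: full window, no streak."""
    return StaircaseState(window_ms=config.start_window_ms, streak=0, decrements_applied=0)


def update(state: StaircaseState, outcome: Outcome, config: StaircaseConfig) -> StaircaseState:
    """Advance the staircase by one classified trial.

    A correct response extends the streak; on reaching ``streak_target`` the
    window drops by ``step_ms`` (clamped at ``floor_ms``) and the streak
    resets.  Any error resets the streak and stagnates the window.
    """
    outcome = Outcome(outcome)
    if outcome is Outcome.CORRECT:
        streak = state.streak + 1
        if streak >= config.streak_target:
            dec = state.decrements_applied + 1
            window = max(config.floor_ms, config.start_window_ms - dec * config.step_ms)
            return StaircaseState(window_ms=window, streak=0, decrements_applied=dec)
        return replace(state, streak=streak)
    # COMMISSION or OMISSION: stagnation
    return replace(state, streak=0)


def reset_streak(state: StaircaseState) -> StaircaseState:
    """Reset the streak without touching the window (hidden-level boundary)."""
    return replace(state, streak=0)
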