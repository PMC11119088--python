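"""Session runner: iterate a schedule, classify responses, drive the staircase.

One call to :func:`run_session` plays a full session of either condition
against a *responder* — any callable ``responder(spec, window_ms, rng) ->
(response, rt_ms)`` — and returns an ordered event record of every trial.

Classification follows the deadline rule: a wrong-direction press inside the
window is a commission error; no press, or a press after the window closes,
is an omission.  In the gamified condition each correct answer drops a
treasure into the jar and each error lets the opponent take one back
(clamped at an empty jar); the response window follows the staircase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from . import staircase as _staircase
from .enums import Condition, Congruency, Direction, Feedback, Outcome, OrderPosition, Phase, Response
from .schedule import TaskConfig, TrialSpec, generate_schedule

__all__ = ["TrialResult", "Session", "classify", "update_jar", "run_session", "Responder"]

Responder = Callable[[TrialSpec, float, np.random.Generator], tuple[Response, Optional[float]]]


@dataclass(frozen=True)
class TrialResult:
    """Observed outcome of one trial.

    ``rt_ms`` is present iff a response landed inside the window; late
    presses are recorded as non-responses.  ``practice_repeat`` counts how
    many times the practice block had been re-presented when this trial ran
    (0 on the first pass; always 0 for test trials).
    """

    spec: TrialSpec
    window_ms: float
    response: Response
    rt_ms: Optional[float]
    outcome: Outcome
    jar_count: int
    feedback: Feedback
    practice_repeat: int = 0
    iti_ms: float = 450.0


@dataclass
class Session:
    """One child x one condition: ordered trial results plus self-report."""

    child_id: str
    age_years: Optional[int]
    condition: Condition
    order_position: Optional[OrderPosition]
    trials: list[TrialResult]
    enjoyment: Optional[int] = None
    preferred: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.enjoyment is not None and self.enjoyment not in (1, 2, 3, 4, 5):
            raise ValueError("enjoyment rating must be an integer 1-5")

    @property
    def test_trials(self) -> list[TrialResult]:
        return [t for t in self.trials if t.spec.phase is Phase.TEST]

    @property
    def practice_trials(self) -> list[TrialResult]:
        return [t for t in self.trials if t.spec.phase is Phase.PRACTICE]


def classify(
    spec: TrialSpec,
    response: Response,
    rt_ms: Optional[float],
    window_ms: float,
) -> Outcome:
    """Classify one trial as CORRECT, COMMISSION, or OMISSION.

    A press after the window closed is coerced to OMISSION: the deadline
    defines the omission, not the absence of a press.
    """
    response = Response(response)
    if (response is Response.NONE) != (rt_ms is None):
        raise ValueError("rt_ms must be absent exactly when response is NONE")
    if response is Response.NONE:
        return Outcome.OMISSION
    if rt_ms < 0:
        raise ValueError(f"negative reaction time ({rt_ms} ms): corrupt input")
    if rt_ms > window_ms:
        return Outcome.OMISSION
    if response.value == spec.target_direction.value:
        return Outcome.CORRECT
    return Outcome.COMMISSION


def update_jar(jar_count: int, outcome: Outcome) -> int:
    """Reward-jar transition: +1 treasure on CORRECT, -1 on any error, floor 0."""
    if jar_count < 0:
        raise ValueError("jar_count may not be negative")
    if Outcome(outcome) is Outcome.CORRECT:
        return jar_count + 1
    return max(0, jar_count - 1)


def _play_trial(
    spec: TrialSpec,
    window_ms: float,
    responder: Responder,
    rng: np.random.Generator,
    jar_count: int,
    track_jar: bool,
    practice_repeat: int,
    iti_ms: float,
) -> TrialResult:
    try:
        response, rt_ms = responder(spec, window_ms, rng)
        response = Response(response)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"responder returned malformed output at trial {spec.index}: {exc}") from exc
    if (response is Response.NONE) != (rt_ms is None):
        raise ValueError(
            f"responder returned malformed output at trial {spec.index}: "
            "rt must be absent exactly when response is NONE"
        )
    outcome = classify(spec, response, rt_ms, window_ms)
    if outcome is Outcome.OMISSION:
        # late or absent presses are recorded as non-responses
        response, rt_ms = Response.NONE, None
    if track_jar:
        jar_count = update_jar(jar_count, outcome)
    return TrialResult(
        spec=spec,
        window_ms=window_ms,
        response=response,
        rt_ms=rt_ms,
        outcome=outcome,
        jar_count=jar_count,
        feedback=Feedback.POSITIVE if outcome is Outcome.CORRECT else Feedback.NEGATIVE,
        practice_repeat=practice_repeat,
        iti_ms=iti_ms,
    )


def run_session(
    config: TaskConfig,
    schedule: Optional[Sequence[TrialSpec]] = None,
    responder: Responder = None,
    rng: Optional[np.random.Generator] = None,
    child_id: str = "anon",
    age_years: Optional[int] = None,
    order_position: Optional[OrderPosition] = None,
) -> Session:
    """Play one full session (practice block, then test block).

    The practice block is re-presented (same trials, up to
    ``max_practice_repeats`` extra passes) until at least
    ``practice_pass_min_correct`` responses in a pass are correct.  Test
    windows come from ``fixed_window_ms`` in the traditional condition and
    from the staircase in the gamified condition; the reward jar runs only
    in the gamified condition.
    """
    if responder is None:
        raise TypeError("a responder callable is required")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if schedule is None:
        schedule = generate_schedule(config)
    practice = [s for s in schedule if s.phase is Phase.PRACTICE]
    test = [s for s in schedule if s.phase is Phase.TEST]
    if len(practice) != config.n_practice or len(test) != config.n_test:
        raise ValueError("schedule is inconsistent with the task configuration")

    gamified = config.condition is Condition.GAMIFIED
    trials: list[TrialResult] = []

    for attempt in range(1 + config.max_practice_repeats):
        n_correct = 0
        for spec in practice:
            result = _play_trial(
                spec, config.practice_window_ms, responder, rng,
                jar_count=0, track_jar=False, practice_repeat=attempt,
                iti_ms=config.iti_ms,
            )
            trials.append(result)
            n_correct += result.outcome is Outcome.CORRECT
        if n_correct >= config.practice_pass_min_correct:
            break

    jar = 0
    state = _staircase.init_state(config.staircase) if gamified else None
    for spec in test:
        window = state.window_ms if gamified else config.fixed_window_ms
        result = _play_trial(
            spec, window, responder, rng,
            jar_count=jar, track_jar=gamified, practice_repeat=0,
            iti_ms=config.iti_ms,
        )
        trials.append(result)
        if gamified:
            jar = result.jar_count
            state = _staircase.update(state, result.outcome, config.staircase)
            sc = config.staircase
            if sc.level_reset and (spec.index - config.n_practice + 1) % sc.streak_target == 0:
                state = _staircase.reset_streak(state)

    return Session(
        child_id=child_id,
        age_years=age_years,
        condition=config.condition,
        order_position=order_position,
        trials=trials,
    )
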