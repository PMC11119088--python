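"""End-to-end simulated studies: cohort -> sessions -> metrics -> statistics.

:func:`simulate_study` replays the full within-subject design on a
synthetic cohort: every child plays both conditions in counterbalanced
order, rates enjoyment after each, and states a would-play-again
preference at the end.  All randomness descends from one seed through
spawned substreams, so cohorts are reproducible and per-child streams are
independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import Session, run_session
from .enums import Condition, OrderPosition, Preference
from .psychstats import StudyReport, run_study_analysis
from .respondent import (
    CALIBRATIONS,
    Calibration,
    ChildProfile,
    make_cohort,
    make_responder,
    profiles_to_frame,
    sample_enjoyment,
    sample_preference,
)
from .schedule import TaskConfig, generate_schedule
from .scoring import metrics_frame
from .staircase import StaircaseConfig

__all__ = ["StudyData", "simulate_study", "analyze_study"]


@dataclass
class StudyData:
    """Everything one simulated study produced."""

    profiles: list[ChildProfile]
    sessions: list[Session]
    preference: pd.Series  # child_id -> Preference value

    @property
    def metrics(self) -> pd.DataFrame:
        """Per-session metrics joined with the children's covariates."""
        m = metrics_frame(self.sessions)
        cov = profiles_to_frame(self.profiles)[
            ["child_id", "ability_z", "verbal_score", "matrix_score"]
        ]
        return m.merge(cov, on="child_id", how="left")


def _task_config(condition: Condition, base: Optional[TaskConfig]) -> TaskConfig:
    if base is not None:
        return base
    if condition is Condition.GAMIFIED:
        return TaskConfig(condition=Condition.GAMIFIED, staircase=StaircaseConfig())
    return TaskConfig(condition=Condition.TRADITIONAL)


def simulate_study(
    n_children: int = 20,
    seed: int = 0,
    calibration: str | Calibration = "preschool2024",
    conditions: Sequence[Condition] = (Condition.TRADITIONAL, Condition.GAMIFIED),
    age_mix: Optional[dict[int, float]] = None,
    traditional_config: Optional[TaskConfig] = None,
    gamified_config: Optional[TaskConfig] = None,
) -> StudyData:
    """Simulate the full two-condition study on a fresh synthetic cohort.

    Condition order is counterbalanced: even-indexed children play the
    gamified version first, odd-indexed children the traditional one.  Each
    child x condition session draws its trial schedule and its responses
    from dedicated substreams of ``seed``.
    """
    conditions = [Condition(c) for c in conditions]
    profiles = make_cohort(n=n_children, age_mix=age_mix, calibration=calibration, seed=seed)
    # independent branch of the seed tree for session-level randomness
    session_streams = np.random.SeedSequence([seed, 1]).spawn(n_children)

    sessions: list[Session] = []
    pref: dict[str, str] = {}
    for i, profile in enumerate(profiles):
        child_streams = session_streams[i].spawn(2 * len(conditions) + 2)
        ordered = list(conditions)
        if len(ordered) == 2 and i % 2 == 0:
            ordered = ordered[::-1]  # gamified first for even-indexed children
        child_sessions = []
        for j, cond in enumerate(ordered):
            config = _task_config(cond, gamified_config if cond is Condition.GAMIFIED else traditional_config)
            sched_rng = np.random.default_rng(child_streams[2 * j])
            play_rng = np.random.default_rng(child_streams[2 * j + 1])
            schedule = generate_schedule(config, rng=sched_rng)
            session = run_session(
                config,
                schedule=schedule,
                responder=make_responder(profile),
                rng=play_rng,
                child_id=profile.child_id,
                age_years=profile.age_years,
                order_position=OrderPosition.FIRST if j == 0 else OrderPosition.SECOND,
            )
            child_sessions.append(session)
        rate_rng = np.random.default_rng(child_streams[-2])
        for session in child_sessions:
            session.enjoyment = sample_enjoyment(profile, session.condition, rate_rng, calibration)
        if len(ordered) == 2:
            choice = sample_preference(profile, np.random.default_rng(child_streams[-1]), calibration)
            pref[profile.child_id] = choice.value
            for session in child_sessions:
                session.preferred = (
                    (choice is Preference.GA and session.condition is Condition.GAMIFIED)
                    or (choice is Preference.FLANKER and session.condition is Condition.TRADITIONAL)
                )
        sessions.extend(child_sessions)

    return StudyData(
        profiles=profiles,
        sessions=sessions,
        preference=pd.Series(pref, name="preference"),
    )


def analyze_study(study: StudyData) -> StudyReport:
    """Run the complete statistics battery on a simulated study."""
    cov = profiles_to_frame(study.profiles)[["child_id", "verbal_score", "matrix_score"]]
    return run_study_analysis(study.metrics, covariates=cov, preference=study.preference)
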