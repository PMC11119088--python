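"""Trial sequence generation for both assessment conditions.

A session consists of a short practice block (congruent/incongruent mixed
half and half, with feedback) followed by a test block with roughly a 2:1
congruent-to-incongruent ratio.  In the gamified condition the test block is
additionally partitioned into consecutive hidden levels of
``streak_target`` trials each, aligned with the staircase controller.

Sequences are reproducible: the same :class:`TaskConfig` (including its
seed) always yields the same ordered list of :class:`TrialSpec`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .enums import Condition, Congruency, Direction, Phase
from .staircase import StaircaseConfig

__all__ = ["TaskConfig", "TrialSpec", "generate_schedule", "schedule_to_csv", "schedule_from_csv"]

#: Longest permitted run of identical congruency or identical target direction.
MAX_RUN_LENGTH = 3

_SHUFFLE_ATTEMPTS = 20000


@dataclass(frozen=True)
class TaskConfig:
    """Full parameterization of one session of either condition.

    Durations are milliseconds.  ``staircase`` is required for the gamified
    condition (a default one is attached automatically) and ignored in the
    traditional condition, where every test trial uses ``fixed_window_ms``.
    """

    condition: Condition
    n_practice: int = 8
    n_test: int = 42
    congruent_fraction: float = 2.0 / 3.0
    iti_ms: float = 450.0
    fixed_window_ms: float = 1700.0
    staircase: Optional[StaircaseConfig] = None
    practice_window_ms: float = 1700.0
    practice_pass_min_correct: int = 6
    max_practice_repeats: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        if self.n_practice < 0 or self.n_test < 0:
            raise ValueError("trial counts may not be negative")
        if not 0.0 < self.congruent_fraction < 1.0:
            raise ValueError("congruent_fraction must lie strictly between 0 and 1")
        for name in ("iti_ms", "fixed_window_ms", "practice_window_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_practice_repeats < 0:
            raise ValueError("max_practice_repeats may not be negative")
        if not 0 <= self.practice_pass_min_correct <= self.n_practice:
            raise ValueError("practice_pass_min_correct must lie in [0, n_practice]")
        if self.condition is Condition.GAMIFIED:
            if self.staircase is None:
                object.__setattr__(self, "staircase", StaircaseConfig())
            sc = self.staircase
            if self.n_test % sc.streak_target != 0:
                raise ValueError(
                    f"n_test ({self.n_test}) is not divisible by the hidden-level "
                    f"size ({sc.streak_target})"
                )
            if sc.streak_target * sc.n_levels != self.n_test:
                raise ValueError(
                    f"streak_target * n_levels ({sc.streak_target * sc.n_levels}) "
                    f"must equal n_test ({self.n_test})"
                )


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled stimulus: position, phase, congruency, target direction.

    ``level_index`` is the hidden level (0-based, test block of the gamified
    condition only) and is None elsewhere.
    """

    index: int
    phase: Phase
    congruency: Congruency
    target_direction: Direction
    level_index: Optional[int] = None


def _largest_remainder_split(n: int, fraction: float) -> tuple[int, int]:
    """Split ``n`` into two integer parts in ratio fraction : 1-fraction.

    Leftover units go to the class with the largest fractional remainder;
    ties favor the first (congruent) class.
    """
    quotas = np.array([fraction * n, (1.0 - fraction) * n])
    base = np.floor(quotas).astype(int)
    leftover = n - int(base.sum())
    if leftover:
        remainders = quotas - base
        # stable argsort descending; index 0 (congruent) wins ties
        order = np.argsort(-remainders, kind="stable")
        for k in order[:leftover]:
            base[k] += 1
    return int(base[0]), int(base[1])


def _direction_counts(n: int) -> tuple[int, int]:
    """50:50 left/right split; an odd count gives the extra trial to LEFT."""
    n_right = n // 2
    return n - n_right, n_right


def _max_run(values: Sequence) -> int:
    longest = run = 0
    prev = object()
    for v in values:
        run = run + 1 if v == prev else 1
        prev = v
        longest = max(longest, run)
    return longest


def _sample_congruency_order(
    n_cong: int, n_incong: int, rng: np.random.Generator
) -> list[Congruency]:
    """Sample uniformly among congruency orders with no run longer than
    MAX_RUN_LENGTH, by completion-counting dynamic programming.

    At each position the next congruency is drawn with probability
    proportional to the number of valid completions, which yields the
    uniform distribution over all constraint-satisfying orders.
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def completions(c: int, i: int, last: int, run: int) -> int:
        # last: 0 = congruent, 1 = incongruent, -1 = none yet
        if c == 0 and i == 0:
            return 1
        total = 0
        if c > 0 and not (last == 0 and run >= MAX_RUN_LENGTH):
            total += completions(c - 1, i, 0, run + 1 if last == 0 else 1)
        if i > 0 and not (last == 1 and run >= MAX_RUN_LENGTH):
            total += completions(c, i - 1, 1, run + 1 if last == 1 else 1)
        return total

    if completions(n_cong, n_incong, -1, 0) == 0:
        raise ValueError(
            f"no ordering of {n_cong} congruent / {n_incong} incongruent trials "
            f"satisfies the run-length constraint ({MAX_RUN_LENGTH})"
        )
    order: list[Congruency] = []
    c, i, last, run = n_cong, n_incong, -1, 0
    while c + i > 0:
        w_c = w_i = 0
        if c > 0 and not (last == 0 and run >= MAX_RUN_LENGTH):
            w_c = completions(c - 1, i, 0, run + 1 if last == 0 else 1)
        if i > 0 and not (last == 1 and run >= MAX_RUN_LENGTH):
            w_i = completions(c, i - 1, 1, run + 1 if last == 1 else 1)
        take_cong = rng.random() < w_c / (w_c + w_i)
        if take_cong:
            order.append(Congruency.CONGRUENT)
            run = run + 1 if last == 0 else 1
            last, c = 0, c - 1
        else:
            order.append(Congruency.INCONGRUENT)
            run = run + 1 if last == 1 else 1
            last, i = 1, i - 1
    return order


def _build_block(
    n: int, fraction: float, rng: np.random.Generator
) -> list[tuple[Congruency, Direction]]:
    """Assemble and shuffle one block subject to the run-length constraints."""
    if n == 0:
        return []
    n_cong, n_incong = _largest_remainder_split(n, fraction)
    congr_order = _sample_congruency_order(n_cong, n_incong, rng)
    # balanced directions within each congruency class, shuffled until the
    # global direction run constraint holds (acceptance is high for a
    # near-50:50 direction mix, so plain rejection suffices here)
    dirs = {}
    for congr, count in ((Congruency.CONGRUENT, n_cong), (Congruency.INCONGRUENT, n_incong)):
        n_left, n_right = _direction_counts(count)
        dirs[congr] = [Direction.LEFT] * n_left + [Direction.RIGHT] * n_right
    for _ in range(_SHUFFLE_ATTEMPTS):
        pools = {
            c: [v[k] for k in rng.permutation(len(v))] for c, v in dirs.items()
        }
        block = [(congr, pools[congr].pop()) for congr in congr_order]
        if _max_run([d for _, d in block]) <= MAX_RUN_LENGTH:
            return block
    raise RuntimeError(
        "could not find a direction assignment satisfying the run-length constraint"
    )


def generate_schedule(config: TaskConfig, rng: Optional[np.random.Generator] = None) -> list[TrialSpec]:
    """Generate the ordered practice + test sequence for one session.

    The practice block is half congruent, half incongruent (extra trial to
    congruent when odd), intermixed; the test block realizes
    ``congruent_fraction`` by largest-remainder rounding (28 congruent / 14
    incongruent at defaults).  Within each congruency class, target
    directions are balanced as parity allows (extra trial LEFT).  Order is
    shuffled under the seed with no more than three consecutive trials of
    the same congruency or the same target direction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    specs: list[TrialSpec] = []
    practice = _build_block(config.n_practice, 0.5, rng)
    for i, (congr, direc) in enumerate(practice):
        specs.append(TrialSpec(index=i, phase=Phase.PRACTICE, congruency=congr, target_direction=direc))
    test = _build_block(config.n_test, config.congruent_fraction, rng)
    block = config.staircase.streak_target if (
        config.condition is Condition.GAMIFIED and config.staircase is not None
    ) else None
    for pos, (congr, direc) in enumerate(test):
        specs.append(
            TrialSpec(
                index=config.n_practice + pos,
                phase=Phase.TEST,
                congruency=congr,
                target_direction=direc,
                level_index=pos // block if block else None,
            )
        )
    return specs


def schedule_to_csv(specs: Sequence[TrialSpec], path: str | Path) -> None:
    """Write a schedule as CSV (one row per trial)."""
    df = pd.DataFrame(
        {
            "index": [s.index for s in specs],
            "phase": [s.phase.value for s in specs],
            "congruency": [s.congruency.value for s in specs],
            "target": [s.target_direction.value for s in specs],
            "level_index": [s.level_index for s in specs],
        }
    )
    df.to_csv(path, index=False)


def schedule_from_csv(path: str | Path) -> list[TrialSpec]:
    """Read a schedule written by :func:`schedule_to_csv`."""
    df = pd.read_csv(path)
    specs = []
    for row in df.to_dict("records"):
        level = None if pd.isna(row["level_index"]) else int(row["level_index"])
        specs.append(
            TrialSpec(
                index=int(row["index"]),
                phase=Phase(row["phase"]),
                congruency=Congruency(row["congruency"]),
                target_direction=Direction(row["target"]),
                level_index=level,
            )
        )
    return specs
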