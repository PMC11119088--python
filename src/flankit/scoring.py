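"""Per-session performance metrics and conflict scores.

Accuracy is the percentage of correct test trials out of all test trials:
omissions and commissions both count against it.  RT means are taken over
correct trials only by default (commission RTs index a different process
and omissions have none); set ``rt_include_commissions=True`` for a
sensitivity analysis that pools commissions in.

Conflict scores quantify the flanker interference effect:

* RT conflict  = mean incongruent RT - mean congruent RT  (positive = slower
  under conflict)
* accuracy conflict = congruent accuracy - incongruent accuracy  (positive =
  less accurate under conflict)

All arithmetic is carried at full precision; rounding happens only when a
report is rendered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .engine import Session
from .enums import Congruency, Outcome, Phase

__all__ = [
    "SessionMetrics",
    "compute_metrics",
    "conflict_accuracy",
    "conflict_rt",
    "omission_summary",
    "metrics_frame",
]


def conflict_accuracy(acc_congruent: float, acc_incongruent: float) -> float:
    """Accuracy conflict score: congruent minus incongruent accuracy (points)."""
    return acc_congruent - acc_incongruent


def conflict_rt(rt_incongruent_ms: float, rt_congruent_ms: float) -> float:
    """RT conflict score: mean incongruent minus mean congruent RT (ms)."""
    return rt_incongruent_ms - rt_congruent_ms


@dataclass(frozen=True)
class SessionMetrics:
    """Test-block summary of one session.

    Accuracies are percentages (0-100).  RT fields are None when a
    congruency class has no correct trials (never silently zero), and the
    RT conflict score is None whenever either mean is.
    """

    acc_congruent: float
    acc_incongruent: float
    acc_overall: float
    rt_congruent_ms: Optional[float]
    rt_incongruent_ms: Optional[float]
    conflict_rt_ms: Optional[float]
    conflict_acc: float
    n_omissions: int
    n_commissions: int
    n_test: int


def compute_metrics(session: Session, rt_include_commissions: bool = False) -> SessionMetrics:
    """Score one session's completed test block (practice excluded)."""
    test = session.test_trials
    if not test:
        raise ValueError("session has no test trials; malformed log")
    by_congr = {c: [t for t in test if t.spec.congruency is c] for c in Congruency}
    for c, trials in by_congr.items():
        if not trials:
            raise ValueError(f"session has no {c.value} test trials; malformed log")

    def _acc(trials) -> float:
        return 100.0 * sum(t.outcome is Outcome.CORRECT for t in trials) / len(trials)

    def _rt(trials) -> Optional[float]:
        keep = (Outcome.CORRECT, Outcome.COMMISSION) if rt_include_commissions else (Outcome.CORRECT,)
        rts = [t.rt_ms for t in trials if t.outcome in keep and t.rt_ms is not None]
        return float(np.mean(rts)) if rts else None

    acc_c = _acc(by_congr[Congruency.CONGRUENT])
    acc_i = _acc(by_congr[Congruency.INCONGRUENT])
    rt_c = _rt(by_congr[Congruency.CONGRUENT])
    rt_i = _rt(by_congr[Congruency.INCONGRUENT])
    return SessionMetrics(
        acc_congruent=acc_c,
        acc_incongruent=acc_i,
        acc_overall=_acc(test),
        rt_congruent_ms=rt_c,
        rt_incongruent_ms=rt_i,
        conflict_rt_ms=conflict_rt(rt_i, rt_c) if rt_c is not None and rt_i is not None else None,
        conflict_acc=conflict_accuracy(acc_c, acc_i),
        n_omissions=sum(t.outcome is Outcome.OMISSION for t in test),
        n_commissions=sum(t.outcome is Outcome.COMMISSION for t in test),
        n_test=len(test),
    )


def metrics_frame(sessions: Iterable[Session], rt_include_commissions: bool = False) -> pd.DataFrame:
    """One row per session: identifiers, self-report, and all metrics."""
    rows = []
    for s in sessions:
        m = compute_metrics(s, rt_include_commissions=rt_include_commissions)
        rows.append(
            {
                "child_id": s.child_id,
                "age_years": s.age_years,
                "condition": s.condition.value,
                "order_position": s.order_position.value if s.order_position else None,
                "enjoyment": s.enjoyment,
                "preferred": s.preferred,
                "acc_congruent": m.acc_congruent,
                "acc_incongruent": m.acc_incongruent,
                "acc_overall": m.acc_overall,
                "rt_congruent_ms": m.rt_congruent_ms,
                "rt_incongruent_ms": m.rt_incongruent_ms,
                "conflict_rt_ms": m.conflict_rt_ms,
                "conflict_acc": m.conflict_acc,
                "n_omissions": m.n_omissions,
                "n_commissions": m.n_commissions,
                "n_test": m.n_test,
            }
        )
    return pd.DataFrame(rows)


def omission_summary(sessions: Iterable[Session]) -> pd.DataFrame:
    """Mean and SD (n-1 denominator) of omission counts per age x condition.

    Cells with a single session report SD as missing (undefined at n=1);
    empty cells are simply absent from the table.
    """
    rows = [
        {
            "age_years": s.age_years,
            "condition": s.condition.value,
            "n_omissions": compute_metrics(s).n_omissions,
        }
        for s in sessions
    ]
    if not rows:
        raise ValueError("no sessions to summarize")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["age_years", "condition"])["n_omissions"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out
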