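"""JSONL event logs: one session header plus one record per trial.

Trial records carry the keys, in fixed order: session_id, child_id,
age_years, condition, order_position, trial_index, phase, practice_repeat,
level_index, congruency, target, window_ms, response, rt_ms, outcome,
jar_count, iti_ms.  ``rt_ms`` is omitted on omission trials and the reader
tolerates its absence.  A leading header record (``record_type: "session"``)
carries the session-level enjoyment rating and preference flag so a file
round-trips to an identical :class:`~flankit.engine.Session`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

from .engine import Session, TrialResult
from .enums import Condition, Congruency, Direction, Feedback, Outcome, OrderPosition, Phase, Response
from .schedule import TrialSpec

__all__ = ["session_id", "write_sessions", "read_sessions"]


def session_id(session: Session) -> str:
    return f"{session.child_id}-{session.condition.value}"


def _trial_record(session: Session, sid: str, trial: TrialResult) -> dict:
    rec = {
        "session_id": sid,
        "child_id": session.child_id,
        "age_years": session.age_years,
        "condition": session.condition.value,
        "order_position": session.order_position.value if session.order_position else None,
        "trial_index": trial.spec.index,
        "phase": trial.spec.phase.value,
        "practice_repeat": trial.practice_repeat,
        "level_index": trial.spec.level_index,
        "congruency": trial.spec.congruency.value,
        "target": trial.spec.target_direction.value,
        "window_ms": trial.window_ms,
        "response": trial.response.value,
    }
    if trial.rt_ms is not None:
        rec["rt_ms"] = trial.rt_ms
    rec["outcome"] = trial.outcome.value
    rec["jar_count"] = trial.jar_count
    rec["iti_ms"] = trial.iti_ms
    return rec


def write_sessions(sessions: Iterable[Session], path: str | Path) -> None:
    """Write sessions to one JSONL file, headers interleaved before trials."""
    path = Path(path)
    with path.open("w") as fh:
        for session in sessions:
            sid = session_id(session)
            header = {
                "record_type": "session",
                "session_id": sid,
                "child_id": session.child_id,
                "age_years": session.age_years,
                "condition": session.condition.value,
                "order_position": session.order_position.value if session.order_position else None,
                "enjoyment": session.enjoyment,
                "preferred": session.preferred,
                "n_trials": len(session.trials),
            }
            fh.write(json.dumps(header) + "\n")
            for trial in session.trials:
                fh.write(json.dumps(_trial_record(session, sid, trial)) + "\n")


def _trial_from_record(rec: dict) -> TrialResult:
    level = rec.get("level_index")
    spec = TrialSpec(
        index=int(rec["trial_index"]),
        phase=Phase(rec["phase"]),
        congruency=Congruency(rec["congruency"]),
        target_direction=Direction(rec["target"]),
        level_index=None if level is None else int(level),
    )
    outcome = Outcome(rec["outcome"])
    return TrialResult(
        spec=spec,
        window_ms=float(rec["window_ms"]),
        response=Response(rec["response"]),
        rt_ms=float(rec["rt_ms"]) if rec.get("rt_ms") is not None else None,
        outcome=outcome,
        jar_count=int(rec["jar_count"]),
        feedback=Feedback.POSITIVE if outcome is Outcome.CORRECT else Feedback.NEGATIVE,
        practice_repeat=int(rec.get("practice_repeat", 0)),
        iti_ms=float(rec.get("iti_ms", 450.0)),
    )


def read_sessions(path: str | Path) -> list[Session]:
    """Read a JSONL log back into Session objects (trial order preserved)."""
    sessions: dict[str, Session] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            if rec.get("record_type") == "session":
                sid = rec["session_id"]
                sessions[sid] = Session(
                    child_id=rec["child_id"],
                    age_years=rec["age_years"],
                    condition=Condition(rec["condition"]),
                    order_position=OrderPosition(rec["order_position"]) if rec.get("order_position") else None,
                    trials=[],
                    enjoyment=rec.get("enjoyment"),
                    preferred=rec.get("preferred"),
                )
                continue
            sid = rec["session_id"]
            if sid not in sessions:
                # trial-only file (no header): reconstruct session shell
                sessions[sid] = Session(
                    child_id=rec["child_id"],
                    age_years=rec.get("age_years"),
                    condition=Condition(rec["condition"]),
                    order_position=OrderPosition(rec["order_position"]) if rec.get("order_position") else None,
                    trials=[],
                )
            sessions[sid].trials.append(_trial_from_record(rec))
    return list(sessions.values())
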