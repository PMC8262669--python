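"""Deterministic replay of event streams into the data store.

:func:`run_events` feeds each patient's chronological stream through the
session scheduler, scores tapping trials, and writes home (``H``) records
into an append-only journal.  Tasks attempted on an expired or never-opened
session, and incomplete records, are rejected and counted — never partially
stored.  Replaying the same stream twice yields byte-identical stores.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Mapping, Optional

from . import events as ev
from .fittest import (
    FitTestTrial,
    KeystrokeEvent,
    TrialRejected,
    UndefinedScore,
    score_trial,
    validate_trial,
)
from .interaction import InteractionEvent
from .protocol import AnchorKind, Protocol, SessionKind, TaskKind
from .scheduler import (
    AnchorEvent,
    SchedulerError,
    SchedulerState,
    TaskRecord,
    complete_task,
    expire,
    ingest_anchor,
)
from .store import Journal, Record, append

__all__ = ["RunResult", "run_events", "touch_logs"]

_TASK_TO_RECORD_TYPE = {
    "subjective_scales": "scales",
    "fit_test": "fit_test",
    "sleep_diary": "sleep_diary",
}


@dataclasses.dataclass
class RunResult:
    journal: Journal
    states: dict  # patient_id -> SchedulerState
    completed: int = 0
    rejected: int = 0
    expired: int = 0
    rejections: list = dataclasses.field(default_factory=list)

    @property
    def records(self) -> list[Record]:
        return list(self.journal.records)


def _find_instance(state: SchedulerState, kind: SessionKind, day: int, now: dt.datetime):
    if kind is SessionKind.NAP:
        live = [
            i
            for i in state.instances
            if i.kind is SessionKind.NAP and i.study_day == day and i.is_due(now)
        ]
        return live[0] if live else None
    return state.find(kind, day)


def _score_hand(hand: str, raw_events: list[dict], target_keys=("s", ";")):
    trial = FitTestTrial(
        hand=hand,  # type: ignore[arg-type]
        target_keys=tuple(target_keys),  # type: ignore[arg-type]
        events=tuple(
            KeystrokeEvent(e["key"], float(e["down_ms"]), float(e["up_ms"]))
            for e in raw_events
        ),
    )
    ok, reason = validate_trial(trial)
    if not ok:
        raise TrialRejected(reason)
    return score_trial(trial)


def run_events(
    stream: Iterable[dict],
    protocols: Mapping[str, Protocol],
    cohort: Mapping[str, str],
    journal: Optional[Journal] = None,
) -> RunResult:
    """Replay a cohort event stream into a journal.

    ``protocols`` maps version id -> protocol; ``cohort`` maps patient id ->
    version.  The tapping task yields one record per hand (so the portal's
    hand filter applies); the task duration is carried on the left-hand
    record to keep the per-task workload counted once.
    """
    journal = journal if journal is not None else Journal()
    result = RunResult(journal=journal, states={})

    for pid, events in ev.by_patient(stream).items():
        version = cohort.get(pid)
        if version is None:
            raise ValueError(f"patient {pid} missing from cohort assignment")
        protocol = protocols[version]
        state = SchedulerState(patient_id=pid, protocol=protocol)
        result.states[pid] = state
        touch_seq = 0

        for event in events:
            now = dt.datetime.fromisoformat(event["timestamp"])
            payload = event["payload"]
            _, newly = expire(state, now)
            result.expired += len(newly)

            if event["event_type"] == "anchor":
                anchor = AnchorEvent(
                    kind=AnchorKind(payload["kind"]),
                    at=now,
                    study_day=int(payload["study_day"]),
                )
                ingest_anchor(state, anchor)
                append(
                    journal,
                    Record(
                        record_id=f"{pid}-d{payload['study_day']:02d}-anchor-{payload['kind']}-{now.isoformat()}",
                        patient_id=pid,
                        record_type="anchor",
                        session=None,
                        date=now.date().isoformat(),
                        categorization="H",
                        payload={"kind": payload["kind"], "study_day": payload["study_day"]},
                        created_at=now.isoformat(),
                    ),
                )

            elif event["event_type"] == "task":
                kind = SessionKind(payload["session"])
                day = int(payload["study_day"])
                task_kind = TaskKind(payload["task_kind"])
                instance = _find_instance(state, kind, day, now)
                if instance is None:
                    result.rejected += 1
                    result.rejections.append((pid, day, kind.value, "no session instance"))
                    continue
                record = TaskRecord(
                    task_kind=task_kind,
                    answers=payload.get("answers", {}),
                    hands=payload.get("hands", {}),
                )
                try:
                    scored = None
                    if task_kind is TaskKind.FIT_TEST:
                        scored = {
                            hand: _score_hand(hand, raw)
                            for hand, raw in sorted(record.hands.items())
                        }
                    complete_task(state, instance, task_kind, record, now)
                except (SchedulerError, TrialRejected, UndefinedScore) as exc:
                    result.rejected += 1
                    result.rejections.append((pid, day, kind.value, str(exc)))
                    continue
                result.completed += 1

                base = dict(
                    patient_id=pid,
                    session=kind.value,
                    date=now.date().isoformat(),
                    categorization="H",
                    created_at=now.isoformat(),
                )
                if task_kind is TaskKind.FIT_TEST:
                    for hand, res in sorted(scored.items()):  # type: ignore[union-attr]
                        fit_payload = {
                            "study_day": day,
                            "hand": hand,
                            "KS": res.kinesia_score,
                            "AT": res.akinesia_time_ms,
                            "IS": res.incoordination_score_ms2,
                            "DS": res.dysmetria_score,
                        }
                        if hand == "left" and "duration_s" in payload:
                            fit_payload["duration_s"] = payload["duration_s"]
                        append(
                            journal,
                            Record(
                                record_id=f"{pid}-d{day:02d}-{kind.value}-fit_test-{hand}",
                                record_type="fit_test",
                                payload=fit_payload,
                                **base,
                            ),
                        )
                else:
                    record_type = _TASK_TO_RECORD_TYPE[task_kind.value]
                    rec_payload = {"study_day": day, "answers": record.answers}
                    if "duration_s" in payload:
                        rec_payload["duration_s"] = payload["duration_s"]
                    append(
                        journal,
                        Record(
                            record_id=f"{pid}-d{day:02d}-{kind.value}-{record_type}",
                            record_type=record_type,
                            payload=rec_payload,
                            **base,
                        ),
                    )

            elif event["event_type"] == "touch":
                touch_seq += 1
                append(
                    journal,
                    Record(
                        record_id=f"{pid}-touch-{touch_seq:06d}",
                        patient_id=pid,
                        record_type="interaction",
                        session=payload["session"],
                        date=now.date().isoformat(),
                        categorization="H",
                        payload={
                            "study_day": payload["study_day"],
                            "x": payload["x"],
                            "y": payload["y"],
                            "t": payload["t"],
                            "on_target": payload["on_target"],
                            "target_id": payload.get("target_id"),
                        },
                        created_at=now.isoformat(),
                    ),
                )
    return result


def touch_logs(records: Iterable[Record]) -> dict[str, list[InteractionEvent]]:
    """Rebuild per-patient interaction logs (with session references) from
    stored interaction records, ready for the target-ratio analytics."""
    logs: dict[str, list[InteractionEvent]] = {}
    for record in records:
        if record.record_type != "interaction":
            continue
        p = record.payload
        logs.setdefault(record.patient_id, []).append(
            InteractionEvent(
                x=p["x"],
                y=p["y"],
                timestamp=p["t"],
                on_target=bool(p["on_target"]),
                target_id=p.get("target_id"),
                session=(int(p["study_day"]), record.session),
            )
        )
    return logs
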