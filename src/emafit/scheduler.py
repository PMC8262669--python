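"""Daily session workflow engine.

The scheduler turns patient-generated anchor events (wake time, first
medication intake, afternoon pre-dose, bedtime, nap end) into session
instances with a due time and an expiry time, decides which session is due
at any clock reading, enforces the all-or-nothing task completeness rule,
and tracks the once-daily sleep diary with carryover prompting: the diary is
designated to the after-medications session, and while it is still pending
it is offered again in every later session of the same day.

State transitions are driven purely by the events and `now` readings fed in,
so replaying an identical event sequence reproduces the serialized state
bit for bit.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .protocol import (
    AnchorKind,
    Protocol,
    SessionKind,
    TaskKind,
    validate_response,
)

__all__ = [
    "AnchorEvent",
    "TaskRecord",
    "SessionInstance",
    "SchedulerState",
    "ingest_anchor",
    "expire",
    "next_due",
    "list_selectable",
    "complete_task",
    "diary_pending",
    "is_complete_record",
]

_STATE_PENDING = "pending"
_STATE_OPEN = "open"
_STATE_COMPLETED = "completed"
_STATE_EXPIRED = "expired"
_STATE_SKIPPED = "skipped"


class SchedulerError(ValueError):
    """An operation violated a scheduler precondition."""


@dataclass(frozen=True)
class AnchorEvent:
    kind: AnchorKind
    at: dt.datetime
    study_day: int

    def __post_init__(self) -> None:
        if self.at.tzinfo is None:
            raise SchedulerError("anchor timestamps must be timezone-aware")
        if self.study_day < 0:
            raise SchedulerError("study_day must be >= 0")


@dataclass(frozen=True)
class TaskRecord:
    """A candidate task result submitted for completion.

    ``answers`` maps question id -> value for questionnaire tasks;
    ``hands`` maps "left"/"right" -> scored tapping-trial payload for the
    motor test.  Completeness is checked before anything is stored: partial
    records are discarded entirely.
    """

    task_kind: TaskKind
    answers: dict = field(default_factory=dict)
    hands: dict = field(default_factory=dict)
    started_at: Optional[dt.datetime] = None
    finished_at: Optional[dt.datetime] = None


@dataclass
class SessionInstance:
    kind: SessionKind
    study_day: int
    due_at: dt.datetime
    expires_at: dt.datetime
    state: str = _STATE_PENDING
    tasks_done: dict = field(default_factory=dict)  # task kind value -> ISO timestamp

    def is_live(self) -> bool:
        return self.state in (_STATE_PENDING, _STATE_OPEN)

    def is_due(self, now: dt.datetime) -> bool:
        # Half-open availability window [due_at, expires_at).
        return self.is_live() and self.due_at <= now < self.expires_at

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "study_day": self.study_day,
            "due_at": self.due_at.isoformat(),
            "expires_at": self.expires_at.isoformat(),
            "state": self.state,
            "tasks_done": dict(sorted(self.tasks_done.items())),
        }


@dataclass
class SchedulerState:
    patient_id: str
    protocol: Protocol
    instances: list = field(default_factory=list)
    diary_done_day: dict = field(default_factory=dict)  # study_day -> bool
    _last_anchor: dict = field(default_factory=dict)  # (kind, day) -> datetime

    def find(self, kind: SessionKind, study_day: int) -> Optional[SessionInstance]:
        for inst in self.instances:
            if inst.kind is kind and inst.study_day == study_day and kind is not SessionKind.NAP:
                return inst
        return None

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "protocol_version": self.protocol.version_id,
            "instances": [i.to_dict() for i in self.instances],
            "diary_done_day": {str(k): v for k, v in sorted(self.diary_done_day.items())},
        }

    def digest(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def ingest_anchor(state: SchedulerState, event: AnchorEvent) -> SchedulerState:
    """Create or update the session instance anchored on ``event``.

    A nap-end anchor always opens a fresh on-demand nap instance.  A repeat
    scheduled anchor on the same day must not move backwards in time; when it
    legitimately repeats (e.g. a corrected wake time) the instance is
    re-anchored only while still live.
    """
    key = (event.kind.value, event.study_day)
    prev = state._last_anchor.get(key)
    if prev is not None and event.at < prev:
        raise SchedulerError(
            f"{event.kind.value} anchor at {event.at.isoformat()} precedes an "
            f"earlier same-day anchor at {prev.isoformat()}"
        )
    state._last_anchor[key] = event.at

    for spec in state.protocol.sessions:
        if spec.anchor is not event.kind:
            continue
        due = event.at + dt.timedelta(minutes=spec.offset_min)
        expires = due + dt.timedelta(minutes=spec.window_min)
        if spec.kind is SessionKind.NAP:
            state.instances.append(
                SessionInstance(SessionKind.NAP, event.study_day, due, expires)
            )
            continue
        inst = state.find(spec.kind, event.study_day)
        if inst is None:
            state.instances.append(SessionInstance(spec.kind, event.study_day, due, expires))
        elif inst.is_live():
            inst.due_at, inst.expires_at = due, expires

    # First medication intake closes the on-waking window early: once the
    # morning dose is taken the pre-dose assessment is no longer meaningful.
    if event.kind is AnchorKind.FIRST_MED_INTAKE:
        morning = state.find(SessionKind.ON_WAKING, event.study_day)
        if morning is not None and morning.is_live() and morning.due_at < event.at < morning.expires_at:
            morning.expires_at = event.at
    return state


def expire(state: SchedulerState, now: dt.datetime) -> tuple[SchedulerState, list]:
    """Advance the clock: open instances whose window has started and expire
    those whose window has passed.  Idempotent for a fixed ``now``."""
    newly_expired = []
    for inst in state.instances:
        if not inst.is_live():
            continue
        if inst.expires_at <= now:
            inst.state = _STATE_EXPIRED
            newly_expired.append(inst)
        elif inst.due_at <= now and inst.state == _STATE_PENDING:
            inst.state = _STATE_OPEN
    return state, newly_expired


def _due_sort_key(inst: SessionInstance):
    return (inst.due_at, inst.kind.order)


def next_due(state: SchedulerState, now: dt.datetime) -> Optional[SessionInstance]:
    """The single session the guided workflow proposes at ``now``.

    Requires the automatic session flow (v1.0+); the alpha version instead
    lets the patient pick from :func:`list_selectable`.  Ties between
    simultaneously due instances break on the fixed session-kind order with
    on-demand naps last.
    """
    if not state.protocol.features.auto_session_flow:
        raise SchedulerError("next_due requires auto_session_flow; use list_selectable")
    due = [i for i in state.instances if i.is_due(now)]
    return min(due, key=_due_sort_key) if due else None


def list_selectable(state: SchedulerState, now: dt.datetime) -> list:
    """All currently available (due, unexpired, uncompleted) instances, in
    deterministic order — the alpha-version patient-driven menu."""
    return sorted((i for i in state.instances if i.is_due(now)), key=_due_sort_key)


def is_complete_record(protocol: Protocol, record: TaskRecord) -> tuple[bool, Optional[str]]:
    """All-or-nothing completeness check for a submitted task record."""
    if record.task_kind is TaskKind.FIT_TEST:
        missing = {"left", "right"} - set(record.hands)
        if missing:
            return False, f"missing {'/'.join(sorted(missing))}-hand trial"
        return True, None
    spec = protocol.task(record.task_kind)
    for q in spec.questions:
        if q.id not in record.answers:
            return False, f"unanswered question {q.id}"
        outcome = validate_response(q, record.answers[q.id])
        if not outcome:
            return False, outcome.reason
    extra = set(record.answers) - {q.id for q in spec.questions}
    if extra:
        return False, f"unknown question ids {sorted(extra)}"
    return True, None


def complete_task(
    state: SchedulerState,
    instance: SessionInstance,
    task_kind: TaskKind,
    record: TaskRecord,
    now: dt.datetime,
) -> SchedulerState:
    """Record a fully completed task in an open session.

    Rejects expired or not-yet-due instances, incomplete records, repeat
    completions, and a second diary on the same study day.  On success the
    task is timestamped with ``now``; completing every per-session task of
    the instance marks the session completed.
    """
    if instance.state == _STATE_EXPIRED or instance.expires_at <= now:
        raise SchedulerError("expired")
    in_window = instance.due_at <= now < instance.expires_at
    if task_kind is TaskKind.SLEEP_DIARY:
        # The once-daily diary may ride on any session whose window is still
        # open, including one whose per-session tasks are already done.
        if instance.state == _STATE_SKIPPED or not in_window:
            raise SchedulerError("session not open at this time")
    elif not instance.is_due(now):
        raise SchedulerError("session not open at this time")
    if record.task_kind is not task_kind:
        raise SchedulerError("record task kind mismatch")
    session_spec = state.protocol.session(instance.kind)
    if task_kind is TaskKind.SLEEP_DIARY:
        if state.diary_done_day.get(instance.study_day, False):
            raise SchedulerError("diary already completed today")
    elif task_kind not in session_spec.tasks:
        raise SchedulerError(f"{task_kind.value} is not offered in {instance.kind.value}")
    if task_kind.value in instance.tasks_done:
        raise SchedulerError("task already completed in this session")

    ok, reason = is_complete_record(state.protocol, record)
    if not ok:
        raise SchedulerError(f"incomplete record: {reason}")

    instance.state = _STATE_OPEN
    instance.tasks_done[task_kind.value] = now.isoformat()
    if task_kind is TaskKind.SLEEP_DIARY:
        state.diary_done_day[instance.study_day] = True

    per_session = {
        t.value
        for t in session_spec.tasks
        if state.protocol.task(t).frequency == "per_session"
    }
    if per_session <= set(instance.tasks_done):
        instance.state = _STATE_COMPLETED
    return state


def diary_pending(state: SchedulerState, study_day: int) -> bool:
    """True while no sleep diary has been completed on ``study_day`` — the
    carryover prompt shown in each later session of the day."""
    return not state.diary_done_day.get(study_day, False)


def replay(
    protocol: Protocol,
    patient_id: str,
    events: Iterable[tuple],
) -> SchedulerState:
    """Replay a chronological stream of ``("anchor", AnchorEvent)``,
    ``("tick", now)`` and ``("complete", instance_key, task_kind, record, now)``
    items into a fresh state.  Used for determinism checks and stream replay."""
    state = SchedulerState(patient_id=patient_id, protocol=protocol)
    for item in events:
        op = item[0]
        if op == "anchor":
            ingest_anchor(state, item[1])
        elif op == "tick":
            expire(state, item[1])
        elif op == "complete":
            (kind, day), task_kind, record, now = item[1], item[2], item[3], item[4]
            inst = state.find(kind, day)
            if inst is not None:
                complete_task(state, inst, task_kind, record, now)
        else:
            raise SchedulerError(f"unknown replay op {op!r}")
    return state
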