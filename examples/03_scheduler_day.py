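"""One scheduled day: anchors open sessions, the guided flow proposes the
next due session, the diary carries over, and unattended sessions expire.
"""

import datetime as dt

from emafit import SchedulerState, default_protocol
from emafit.protocol import AnchorKind, SessionKind, TaskKind
from emafit.scheduler import AnchorEvent, TaskRecord, complete_task, expire, ingest_anchor, next_due

TZ = dt.timezone(dt.timedelta(hours=1))
t = lambda h, m=0: dt.datetime(2024, 3, 5, h, m, tzinfo=TZ)

proto = default_protocol("v2.0")
state = SchedulerState(patient_id="demo", protocol=proto)

ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, t(7, 0), study_day=1))
print("woke 07:00 -> on-waking session due", state.find(SessionKind.ON_WAKING, 1).due_at.time())

expire(state, t(7, 45))
print("07:45 guided flow proposes:", next_due(state, t(7, 45)).kind.value)

answers = {}
for q in proto.task(TaskKind.SUBJECTIVE_SCALES).questions:
    answers[q.id] = q.domain.lo if q.domain.kind == "int_range" else q.domain.levels[0]
inst = state.find(SessionKind.ON_WAKING, 1)
complete_task(state, inst, TaskKind.SUBJECTIVE_SCALES, TaskRecord(TaskKind.SUBJECTIVE_SCALES, answers=answers), t(7, 50))
complete_task(state, inst, TaskKind.FIT_TEST, TaskRecord(TaskKind.FIT_TEST, hands={"left": [], "right": []}), t(7, 55))
print("on-waking session state:", inst.state)

ingest_anchor(state, AnchorEvent(AnchorKind.FIRST_MED_INTAKE, t(8, 0), study_day=1))
print("after-medications due:", state.find(SessionKind.AFTER_MEDICATIONS, 1).due_at.time())

_, gone = expire(state, t(23, 0))
print("by 23:00 expired unattended sessions:", [i.kind.value for i in gone])

# The after-medications session expired because its scales/tapping/diary were
# never submitted; an expired session can never be completed later that day.
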