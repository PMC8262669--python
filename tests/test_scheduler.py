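"""Session state machine: anchoring, expiry, completeness, diary carryover."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emafit.protocol import AnchorKind, SessionKind, TaskKind, default_protocol
from emafit.scheduler import (
    AnchorEvent,
    SchedulerError,
    SchedulerState,
    TaskRecord,
    complete_task,
    diary_pending,
    expire,
    ingest_anchor,
    is_complete_record,
    list_selectable,
    next_due,
)


def full_scales_record(protocol) -> TaskRecord:
    answers = {}
    for q in protocol.task(TaskKind.SUBJECTIVE_SCALES).questions:
        if q.domain.kind == "int_range":
            answers[q.id] = q.domain.lo
        else:
            answers[q.id] = q.domain.levels[0]
    return TaskRecord(task_kind=TaskKind.SUBJECTIVE_SCALES, answers=answers)


def full_diary_record(protocol) -> TaskRecord:
    answers = {}
    for q in protocol.task(TaskKind.SLEEP_DIARY).questions:
        if q.domain.kind == "int_range":
            answers[q.id] = q.domain.hi
        elif q.domain.kind == "categorical":
            answers[q.id] = q.domain.levels[-1]
        else:
            answers[q.id] = "22:30"
    return TaskRecord(task_kind=TaskKind.SLEEP_DIARY, answers=answers)


def fit_record() -> TaskRecord:
    return TaskRecord(task_kind=TaskKind.FIT_TEST, hands={"left": [], "right": []})


@pytest.fixture()
def state(v2):
    return SchedulerState(patient_id="p1", protocol=v2)


class TestAnchoring:
    def test_wake_yields_on_waking_due_30_min_later(self, state, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 7), 1))
        inst = state.find(SessionKind.ON_WAKING, 1)
        assert inst.due_at == clock(1, 7, 30)
        assert inst.expires_at > inst.due_at

    def test_first_dose_yields_after_medications_due_60_min_later(self, state, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.FIRST_MED_INTAKE, clock(1, 8), 1))
        assert state.find(SessionKind.AFTER_MEDICATIONS, 1).due_at == clock(1, 9)

    def test_nap_end_opens_nap_immediately(self, state, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.NAP_END, clock(1, 15, 10), 1))
        naps = [i for i in state.instances if i.kind is SessionKind.NAP]
        assert len(naps) == 1 and naps[0].due_at == clock(1, 15, 10)

    def test_backwards_anchor_rejected(self, state, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 7), 1))
        with pytest.raises(SchedulerError, match="precedes"):
            ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 6), 1))

    def test_naive_timestamp_rejected(self):
        with pytest.raises(SchedulerError, match="timezone"):
            AnchorEvent(AnchorKind.WAKE_TIME, dt.datetime(2024, 3, 4, 7), 0)

    def test_med_intake_closes_on_waking_window(self, state, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 7), 1))
        ingest_anchor(state, AnchorEvent(AnchorKind.FIRST_MED_INTAKE, clock(1, 8), 1))
        assert state.find(SessionKind.ON_WAKING, 1).expires_at == clock(1, 8)


class TestNextDue:
    def test_none_before_any_due(self, state, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 7), 1))
        assert next_due(state, clock(1, 7, 15)) is None

    def test_open_session_returned(self, state, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 7), 1))
        assert next_due(state, clock(1, 7, 45)).kind is SessionKind.ON_WAKING

    def test_tie_break_scheduled_before_nap(self, state, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.PRE_AFTERNOON_DOSE, clock(1, 15), 1))
        ingest_anchor(state, AnchorEvent(AnchorKind.NAP_END, clock(1, 15), 1))
        assert next_due(state, clock(1, 15, 5)).kind is SessionKind.AFTERNOON

    def test_alpha_uses_patient_driven_menu(self, clock):
        st_ = SchedulerState(patient_id="p1", protocol=default_protocol("alpha"))
        ingest_anchor(st_, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 7), 1))
        ingest_anchor(st_, AnchorEvent(AnchorKind.NAP_END, clock(1, 7, 30), 1))
        with pytest.raises(SchedulerError, match="auto_session_flow"):
            next_due(st_, clock(1, 8))
        kinds = [i.kind for i in list_selectable(st_, clock(1, 8))]
        assert kinds == [SessionKind.ON_WAKING, SessionKind.NAP]


class TestCompletion:
    def test_full_record_accepted_and_timestamped(self, state, v2, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 7), 1))
        inst = state.find(SessionKind.ON_WAKING, 1)
        complete_task(state, inst, TaskKind.SUBJECTIVE_SCALES, full_scales_record(v2), clock(1, 7, 40))
        assert inst.tasks_done["subjective_scales"] == clock(1, 7, 40).isoformat()

    def test_partial_record_discarded_entirely(self, state, v2, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 7), 1))
        inst = state.find(SessionKind.ON_WAKING, 1)
        record = full_scales_record(v2)
        record.answers.pop("sss")
        with pytest.raises(SchedulerError, match="incomplete"):
            complete_task(state, inst, TaskKind.SUBJECTIVE_SCALES, record, clock(1, 7, 40))
        assert inst.tasks_done == {}

    def test_completion_on_expired_session_rejected(self, state, v2, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 7), 1))
        inst = state.find(SessionKind.ON_WAKING, 1)
        expire(state, clock(1, 11))
        with pytest.raises(SchedulerError, match="expired"):
            complete_task(state, inst, TaskKind.SUBJECTIVE_SCALES, full_scales_record(v2), clock(1, 11))

    def test_session_completed_after_all_per_session_tasks(self, state, v2, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 7), 1))
        inst = state.find(SessionKind.ON_WAKING, 1)
        complete_task(state, inst, TaskKind.SUBJECTIVE_SCALES, full_scales_record(v2), clock(1, 7, 40))
        assert inst.state == "open"
        complete_task(state, inst, TaskKind.FIT_TEST, fit_record(), clock(1, 7, 45))
        assert inst.state == "completed"

    def test_missing_hand_is_incomplete(self, v2):
        ok, reason = is_complete_record(v2, TaskRecord(task_kind=TaskKind.FIT_TEST, hands={"left": []}))
        assert not ok and "right" in reason


class TestDiary:
    def test_pending_until_completed_then_not_offered(self, state, v2, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.FIRST_MED_INTAKE, clock(1, 8), 1))
        inst = state.find(SessionKind.AFTER_MEDICATIONS, 1)
        assert diary_pending(state, 1)
        complete_task(state, inst, TaskKind.SLEEP_DIARY, full_diary_record(v2), clock(1, 9, 10))
        assert not diary_pending(state, 1)
        with pytest.raises(SchedulerError, match="diary already"):
            complete_task(state, inst, TaskKind.SLEEP_DIARY, full_diary_record(v2), clock(1, 9, 20))

    def test_carryover_to_later_session_same_day(self, state, v2, clock):
        """Diary skipped in the morning is accepted in the afternoon session."""
        ingest_anchor(state, AnchorEvent(AnchorKind.PRE_AFTERNOON_DOSE, clock(1, 15), 1))
        inst = state.find(SessionKind.AFTERNOON, 1)
        assert diary_pending(state, 1)
        complete_task(state, inst, TaskKind.SLEEP_DIARY, full_diary_record(v2), clock(1, 15, 30))
        assert not diary_pending(state, 1)

    def test_diary_allowed_after_session_tasks_done(self, state, v2, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.FIRST_MED_INTAKE, clock(1, 8), 1))
        inst = state.find(SessionKind.AFTER_MEDICATIONS, 1)
        complete_task(state, inst, TaskKind.SUBJECTIVE_SCALES, full_scales_record(v2), clock(1, 9, 5))
        complete_task(state, inst, TaskKind.FIT_TEST, fit_record(), clock(1, 9, 10))
        assert inst.state == "completed"
        complete_task(state, inst, TaskKind.SLEEP_DIARY, full_diary_record(v2), clock(1, 9, 15))
        assert not diary_pending(state, 1)

    def test_resets_on_new_study_day(self, state):
        state.diary_done_day[3] = True
        assert not diary_pending(state, 3)
        assert diary_pending(state, 4)


class TestExpiry:
    def test_boundary_is_half_open(self, state, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 7), 1))
        inst = state.find(SessionKind.ON_WAKING, 1)
        _, newly = expire(state, inst.expires_at)
        assert newly == [inst] and inst.state == "expired"

    def test_idempotent(self, state, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 7), 1))
        expire(state, clock(1, 23))
        _, again = expire(state, clock(1, 23))
        assert again == []

    def test_expired_never_reopens(self, state, clock):
        ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(1, 7), 1))
        inst = state.find(SessionKind.ON_WAKING, 1)
        expire(state, clock(1, 23))
        expire(state, clock(2, 1))
        assert inst.state == "expired"

    def test_state_partition(self, state, v2, clock):
        """Every instance is in exactly one state at all times."""
        for day in (1, 2):
            ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, clock(day, 7), day))
            ingest_anchor(state, AnchorEvent(AnchorKind.FIRST_MED_INTAKE, clock(day, 8, 30), day))
        inst = state.find(SessionKind.AFTER_MEDICATIONS, 1)
        complete_task(state, inst, TaskKind.SUBJECTIVE_SCALES, full_scales_record(v2), clock(1, 9, 40))
        complete_task(state, inst, TaskKind.FIT_TEST, fit_record(), clock(1, 9, 45))
        expire(state, clock(2, 9))
        states = [i.state for i in state.instances]
        assert len(states) == 4
        assert sum(s == "completed" for s in states) + sum(s == "expired" for s in states) + sum(
            s in ("open", "pending") for s in states
        ) == len(states)


@st.composite
def day_plans(draw):
    """A random multi-day anchor/completion plan."""
    days = draw(st.integers(min_value=1, max_value=4))
    plan = []
    for day in range(1, days + 1):
        wake_min = draw(st.integers(min_value=0, max_value=90))
        med_gap = draw(st.integers(min_value=35, max_value=120))
        do_scales = draw(st.booleans())
        do_fit = draw(st.booleans())
        delay = draw(st.integers(min_value=1, max_value=25))
        plan.append((day, wake_min, med_gap, do_scales, do_fit, delay))
    return plan


class TestReplayDeterminism:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(plan=day_plans())
    def test_same_events_same_serialized_state(self, v2, plan):
        def build():
            state = SchedulerState(patient_id="p1", protocol=v2)
            tz = dt.timezone(dt.timedelta(hours=1))
            for day, wake_min, med_gap, do_scales, do_fit, delay in plan:
                wake = dt.datetime(2024, 3, 4, 7, 0, tzinfo=tz) + dt.timedelta(
                    days=day, minutes=wake_min
                )
                ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, wake, day))
                med = wake + dt.timedelta(minutes=med_gap)
                ingest_anchor(state, AnchorEvent(AnchorKind.FIRST_MED_INTAKE, med, day))
                inst = state.find(SessionKind.AFTER_MEDICATIONS, day)
                now = inst.due_at + dt.timedelta(minutes=delay)
                expire(state, now)
                if do_scales:
                    complete_task(state, inst, TaskKind.SUBJECTIVE_SCALES, full_scales_record(v2), now)
                if do_fit:
                    complete_task(
                        state, inst, TaskKind.FIT_TEST, fit_record(), now + dt.timedelta(minutes=1)
                    )
                expire(state, wake + dt.timedelta(hours=16))
            return state

        assert build().digest() == build().digest()
        assert build().to_dict() == build().to_dict()

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(plan=day_plans())
    def test_monotone_clock_never_unexpires(self, v2, plan):
        state = SchedulerState(patient_id="p1", protocol=v2)
        tz = dt.timezone(dt.timedelta(hours=1))
        seen_final = {}
        for day, wake_min, med_gap, _s, _f, _d in plan:
            wake = dt.datetime(2024, 3, 4, 7, 0, tzinfo=tz) + dt.timedelta(days=day, minutes=wake_min)
            ingest_anchor(state, AnchorEvent(AnchorKind.WAKE_TIME, wake, day))
            expire(state, wake + dt.timedelta(hours=20))
            for inst in state.instances:
                key = (inst.kind.value, inst.study_day)
                if seen_final.get(key) in ("expired", "completed"):
                    assert inst.state == seen_final[key]
                seen_final[key] = inst.state
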