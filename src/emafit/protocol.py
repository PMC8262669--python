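"""Versioned study-protocol model and expected-workload accounting.

A :class:`Protocol` describes one released version of the home-assessment
application: which sessions exist, which anchors and offsets schedule them,
which tasks each session carries, and the question banks behind the
questionnaire tasks.  Three built-in versions are provided (``alpha``,
``v1.0``, ``v2.0``) differing in feature flags and in the size of the
subjective-scales bank (5 questions in alpha, 11 from v1.0 on).

The home evaluation period spans ``home_nights`` nights: the patient arrives
in the evening of day 0, lives ``home_nights - 1`` full four-session days,
and finishes with the two morning sessions (on waking, after medications) of
the final day.  :func:`expected_tasks` and :func:`expected_questions`
enumerate that calendar to produce the per-patient workload ledger that the
compliance analytics use as denominators.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Iterable, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "VersionId",
    "SessionKind",
    "AnchorKind",
    "TaskKind",
    "Instrument",
    "AnswerDomain",
    "QuestionSpec",
    "TaskSpec",
    "SessionSpec",
    "FeatureFlags",
    "Protocol",
    "TaskLedger",
    "ValidationOutcome",
    "load_protocol",
    "default_config",
    "default_protocol",
    "validate_response",
    "schedule_slots",
    "expected_tasks",
    "expected_questions",
]

VersionId = Literal["alpha", "v1.0", "v2.0"]


class SessionKind(str, enum.Enum):
    ON_WAKING = "on_waking"
    AFTER_MEDICATIONS = "after_medications"
    AFTERNOON = "afternoon"
    EVENING = "evening"
    NAP = "nap"

    @property
    def order(self) -> int:
        """Deterministic tie-break order; nap always last."""
        return _SESSION_ORDER[self]


_SESSION_ORDER = {
    SessionKind.ON_WAKING: 0,
    SessionKind.AFTER_MEDICATIONS: 1,
    SessionKind.AFTERNOON: 2,
    SessionKind.EVENING: 3,
    SessionKind.NAP: 4,
}

SCHEDULED_KINDS = (
    SessionKind.ON_WAKING,
    SessionKind.AFTER_MEDICATIONS,
    SessionKind.AFTERNOON,
    SessionKind.EVENING,
)


class AnchorKind(str, enum.Enum):
    WAKE_TIME = "wake_time"
    FIRST_MED_INTAKE = "first_med_intake"
    PRE_AFTERNOON_DOSE = "pre_afternoon_dose"
    BEDTIME = "bedtime"
    NAP_END = "nap_end"


class TaskKind(str, enum.Enum):
    SUBJECTIVE_SCALES = "subjective_scales"
    FIT_TEST = "fit_test"
    SLEEP_DIARY = "sleep_diary"


class Instrument(str, enum.Enum):
    SCOPA_DC_ITEM = "scopa_dc_item"
    VAS = "vas"
    STANFORD_SLEEPINESS = "stanford_sleepiness"
    DIARY_ITEM = "diary_item"


class AnswerDomain(BaseModel):
    """Closed answer domain for one question: no free-text entry exists.

    ``categorical`` lists its admissible levels, ``int_range`` is the closed
    integer interval [lo, hi], ``timestamp`` accepts an ISO-8601 clock time.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    kind: Literal["categorical", "int_range", "timestamp"]
    levels: Optional[tuple[str, ...]] = None
    lo: Optional[int] = None
    hi: Optional[int] = None

    @model_validator(mode="after")
    def _check_shape(self) -> "AnswerDomain":
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError("categorical domain requires levels")
        elif self.kind == "int_range":
            if self.lo is None or self.hi is None or self.lo > self.hi:
                raise ValueError("int_range domain requires lo <= hi")
        return self


class QuestionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    id: str
    instrument: Instrument
    domain: AnswerDomain
    text: str

    @model_validator(mode="after")
    def _check_instrument_domain(self) -> "QuestionSpec":
        if self.instrument is Instrument.VAS:
            if self.domain.kind != "int_range" or (self.domain.lo, self.domain.hi) != (0, 10):
                raise ValueError(f"question {self.id}: VAS domain must be integers 0-10")
        if self.instrument is Instrument.STANFORD_SLEEPINESS:
            if self.domain.kind != "int_range" or (self.domain.lo, self.domain.hi) != (1, 7):
                raise ValueError(f"question {self.id}: Stanford sleepiness domain must be 1-7")
        return self


class TaskSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    kind: TaskKind
    questions: tuple[QuestionSpec, ...] = ()
    frequency: Literal["per_session", "once_daily"] = "per_session"

    @model_validator(mode="after")
    def _check_task(self) -> "TaskSpec":
        if self.kind is TaskKind.FIT_TEST and self.questions:
            raise ValueError("fit_test carries no questions")
        if self.kind is TaskKind.SLEEP_DIARY:
            if self.frequency != "once_daily":
                raise ValueError("sleep_diary frequency must be once_daily")
            if len(self.questions) != 24:
                raise ValueError("sleep_diary must have 24 questions")
        return self


class SessionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    kind: SessionKind
    anchor: AnchorKind
    offset_min: int = 0
    window_min: int = Field(default=180, gt=0)
    tasks: tuple[TaskKind, ...] = ()

    @model_validator(mode="after")
    def _check_offsets(self) -> "SessionSpec":
        if self.kind is SessionKind.ON_WAKING and self.offset_min != 30:
            raise ValueError("on_waking session is due 30 minutes after waking")
        if self.kind is SessionKind.AFTER_MEDICATIONS and self.offset_min != 60:
            raise ValueError("after_medications session is due 60 minutes after first dose")
        return self


class FeatureFlags(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    auto_session_flow: bool
    kiosk_mode: bool
    interaction_logging: bool
    store_and_forward: bool


class Protocol(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    version_id: VersionId
    sessions: tuple[SessionSpec, ...]
    tasks: tuple[TaskSpec, ...]
    home_nights: int = Field(default=14, ge=0)
    features: FeatureFlags

    @model_validator(mode="after")
    def _check_protocol(self) -> "Protocol":
        kinds = [s.kind for s in self.sessions]
        if sorted(k.value for k in kinds if k is not SessionKind.NAP) != sorted(
            k.value for k in SCHEDULED_KINDS
        ):
            raise ValueError("protocol must define exactly the four scheduled session kinds")
        if SessionKind.NAP not in kinds:
            raise ValueError("protocol must define the on-demand nap session")
        attached = {t for s in self.sessions for t in s.tasks}
        for task in self.tasks:
            if task.kind not in attached:
                raise ValueError(f"task {task.kind.value} is attached to no session")
        expect_auto = self.version_id != "alpha"
        if self.features.auto_session_flow != expect_auto:
            raise ValueError(
                f"auto_session_flow must be {expect_auto} for version {self.version_id}"
            )
        n_scales = len(self.task(TaskKind.SUBJECTIVE_SCALES).questions)
        want = 5 if self.version_id == "alpha" else 11
        if n_scales != want:
            raise ValueError(
                f"subjective_scales bank for {self.version_id} must have {want} questions"
            )
        return self

    def task(self, kind: TaskKind) -> TaskSpec:
        for t in self.tasks:
            if t.kind is kind:
                return t
        raise KeyError(kind)

    def session(self, kind: SessionKind) -> SessionSpec:
        for s in self.sessions:
            if s.kind is kind:
                return s
        raise KeyError(kind)


class TaskLedger(BaseModel):
    """Expected per-patient workload over the home period."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    subjective_scales: int = Field(ge=0)
    fit_test: int = Field(ge=0)
    sleep_diary: int = Field(ge=0)

    @property
    def total_tasks(self) -> int:
        return self.subjective_scales + self.fit_test + self.sleep_diary

    def count(self, kind: TaskKind) -> int:
        return getattr(self, kind.value)


class ValidationOutcome(BaseModel):
    model_config = ConfigDict(frozen=True)

    accepted: bool
    reason: Optional[str] = None

    def __bool__(self) -> bool:
        return self.accepted


# --------------------------------------------------------------------------
# Built-in question banks.  Item texts are package placeholders carrying the
# published instruments, domains and counts; studies override them in config.

def _scales_bank(version: VersionId) -> list[dict]:
    scopa = [
        {
            "id": f"scopa_dc_{i}",
            "instrument": "scopa_dc_item",
            "domain": {"kind": "categorical", "levels": ("0", "1", "2", "3")},
            "text": f"Momentary motor status item {i}",
        }
        for i in range(1, 5)
    ]
    stanford = [
        {
            "id": "sss",
            "instrument": "stanford_sleepiness",
            "domain": {"kind": "int_range", "lo": 1, "hi": 7},
            "text": "How sleepy do you feel right now?",
        }
    ]
    if version == "alpha":
        return scopa + stanford
    vas = [
        {
            "id": f"vas_{name}",
            "instrument": "vas",
            "domain": {"kind": "int_range", "lo": 0, "hi": 10},
            "text": f"Rate your current {name.replace('_', ' ')} (0-10)",
        }
        for name in ("mobility", "tremor", "mood", "anxiety", "fatigue", "pain")
    ]
    return scopa + vas + stanford


def _diary_bank() -> list[dict]:
    items: list[dict] = []
    for i in range(1, 22):
        items.append(
            {
                "id": f"diary_{i:02d}",
                "instrument": "diary_item",
                "domain": {
                    "kind": "categorical",
                    "levels": ("not_at_all", "a_little", "moderately", "a_lot"),
                },
                "text": f"Night/sleep habit item {i}",
            }
        )
    items.append(
        {
            "id": "diary_22_caffeine",
            "instrument": "diary_item",
            "domain": {"kind": "int_range", "lo": 0, "hi": 10},
            "text": "Number of caffeinated drinks yesterday",
        }
    )
    items.append(
        {
            "id": "diary_23_lights_off",
            "instrument": "diary_item",
            "domain": {"kind": "timestamp"},
            "text": "At what time did you turn the lights off?",
        }
    )
    items.append(
        {
            "id": "diary_24_final_wake",
            "instrument": "diary_item",
            "domain": {"kind": "timestamp"},
            "text": "At what time did you wake up for good?",
        }
    )
    return items


_FEATURES: dict[str, dict] = {
    "alpha": dict(
        auto_session_flow=False, kiosk_mode=False,
        interaction_logging=False, store_and_forward=False,
    ),
    "v1.0": dict(
        auto_session_flow=True, kiosk_mode=False,
        interaction_logging=True, store_and_forward=True,
    ),
    "v2.0": dict(
        auto_session_flow=True, kiosk_mode=True,
        interaction_logging=True, store_and_forward=True,
    ),
}


def default_config(version: VersionId = "v2.0", home_nights: int = 14) -> dict:
    """Built-in protocol configuration for one application version."""
    both = ("subjective_scales", "fit_test")
    return {
        "version_id": version,
        "home_nights": home_nights,
        "features": dict(_FEATURES[version]),
        "sessions": [
            {"kind": "on_waking", "anchor": "wake_time", "offset_min": 30,
             "window_min": 180, "tasks": both},
            {"kind": "after_medications", "anchor": "first_med_intake", "offset_min": 60,
             "window_min": 180, "tasks": both + ("sleep_diary",)},
            {"kind": "afternoon", "anchor": "pre_afternoon_dose", "offset_min": 0,
             "window_min": 180, "tasks": both},
            {"kind": "evening", "anchor": "bedtime", "offset_min": 0,
             "window_min": 180, "tasks": both},
            {"kind": "nap", "anchor": "nap_end", "offset_min": 0,
             "window_min": 60, "tasks": both},
        ],
        "tasks": [
            {"kind": "subjective_scales", "frequency": "per_session",
             "questions": _scales_bank(version)},
            {"kind": "fit_test", "frequency": "per_session", "questions": []},
            {"kind": "sleep_diary", "frequency": "once_daily",
             "questions": _diary_bank()},
        ],
    }


def default_protocol(version: VersionId = "v2.0", home_nights: int = 14) -> Protocol:
    return Protocol.model_validate(default_config(version, home_nights))


def load_protocol(config: Union[str, Path, dict]) -> Protocol:
    """Parse and validate a protocol configuration.

    Accepts a mapping, a YAML/JSON string, or a path to a YAML file.  Unknown
    fields are rejected; validation errors name the offending field.
    """
    if isinstance(config, Path) or (
        isinstance(config, str) and "\n" not in config and config.endswith((".yaml", ".yml", ".json"))
    ):
        with open(config, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    elif isinstance(config, str):
        data = yaml.safe_load(config)
    else:
        data = config
    if not isinstance(data, dict):
        raise ValueError("protocol config must be a mapping")
    return Protocol.model_validate(data)


# --------------------------------------------------------------------------
# Workload accounting.

def validate_response(q: QuestionSpec, value: object) -> ValidationOutcome:
    """Accept a candidate answer iff it lies inside the question's domain.

    Booleans are rejected for integer domains (True == 1 is a type artifact,
    not a clinical answer).
    """
    dom = q.domain
    if dom.kind == "categorical":
        if isinstance(value, str) and value in (dom.levels or ()):
            return ValidationOutcome(accepted=True)
        return ValidationOutcome(accepted=False, reason=f"{value!r} not a level of {q.id}")
    if dom.kind == "int_range":
        if isinstance(value, bool) or not isinstance(value, int):
            return ValidationOutcome(accepted=False, reason=f"{q.id} expects an integer")
        if dom.lo <= value <= dom.hi:  # type: ignore[operator]
            return ValidationOutcome(accepted=True)
        return ValidationOutcome(
            accepted=False, reason=f"{value} outside [{dom.lo}, {dom.hi}] for {q.id}"
        )
    # timestamp
    if isinstance(value, str):
        import datetime as _dt

        for fmt in ("%H:%M", "%H:%M:%S"):
            try:
                _dt.datetime.strptime(value, fmt)
                return ValidationOutcome(accepted=True)
            except ValueError:
                continue
        try:
            _dt.datetime.fromisoformat(value)
            return ValidationOutcome(accepted=True)
        except ValueError:
            pass
    return ValidationOutcome(accepted=False, reason=f"{q.id} expects a clock time or ISO timestamp")


def schedule_slots(protocol: Protocol) -> list[tuple[int, SessionKind]]:
    """Enumerate the scheduled (non-nap) session slots of the home period.

    Day 0 contributes only the arrival evening; days ``1 .. home_nights-1``
    are full four-session days; the final morning (day ``home_nights``)
    contributes on-waking and after-medications.  14 nights therefore span
    15 calendar days and yield 4n - 1 = 55 slots.
    """
    n = protocol.home_nights
    if n == 0:
        return []
    slots: list[tuple[int, SessionKind]] = [(0, SessionKind.EVENING)]
    for day in range(1, n):
        slots.extend((day, k) for k in SCHEDULED_KINDS)
    slots.append((n, SessionKind.ON_WAKING))
    slots.append((n, SessionKind.AFTER_MEDICATIONS))
    return slots


def diary_days(protocol: Protocol) -> list[int]:
    """Study days on which a sleep diary is expected: one per home night,
    reported the morning after (days 1 .. home_nights)."""
    return list(range(1, protocol.home_nights + 1))


def expected_tasks(protocol: Protocol) -> TaskLedger:
    """Per-patient expected task counts over the home period.

    Derived by enumerating :func:`schedule_slots`; on-demand nap sessions are
    excluded because they cannot be scheduled a priori.
    """
    counts = {TaskKind.SUBJECTIVE_SCALES: 0, TaskKind.FIT_TEST: 0}
    for _day, kind in schedule_slots(protocol):
        session = protocol.session(kind)
        for task in session.tasks:
            if task in counts:
                counts[task] += 1
    return TaskLedger(
        subjective_scales=counts[TaskKind.SUBJECTIVE_SCALES],
        fit_test=counts[TaskKind.FIT_TEST],
        sleep_diary=len(diary_days(protocol)),
    )


def expected_questions(protocol: Protocol) -> int:
    """Total questions the protocol poses over the home period:
    (scales sessions x scales bank size) + (nights x diary bank size)."""
    ledger = expected_tasks(protocol)
    n_scale_q = len(protocol.task(TaskKind.SUBJECTIVE_SCALES).questions)
    n_diary_q = len(protocol.task(TaskKind.SLEEP_DIARY).questions)
    return ledger.subjective_scales * n_scale_q + ledger.sleep_diary * n_diary_q


def questions_per_full_day(protocol: Protocol) -> int:
    """Questions posed on one full mid-study day (4 scale sets + 1 diary)."""
    n_scale_q = len(protocol.task(TaskKind.SUBJECTIVE_SCALES).questions)
    n_diary_q = len(protocol.task(TaskKind.SLEEP_DIARY).questions)
    return 4 * n_scale_q + n_diary_q


def sweep_domain(domain: AnswerDomain) -> Iterable[object]:
    """Every admissible value of a finite answer domain (test helper for
    exhaustive validation sweeps; timestamp domains are not finite)."""
    if domain.kind == "categorical":
        return list(domain.levels or ())
    if domain.kind == "int_range":
        return list(range(domain.lo, domain.hi + 1))  # type: ignore[arg-type]
    raise ValueError("timestamp domains cannot be enumerated")
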