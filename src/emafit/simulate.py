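"""Synthetic-patient cohort simulator.

Generates everything the engine consumes — anchor events, per-session
adherence decisions, complete questionnaire responses, alternating-tapping
keystroke streams and touch logs — from a single root seed, alongside a
:class:`GroundTruth` object holding the realized per-patient parameters and
per-session adherence draws, so every downstream statistic can be
recomputed independently in tests.

Default conditions emulate the home study the engine was built around:
26 patients on the v2.0 protocol for 14 nights, per-session adherence
around 0.9 with a mild multiplicative within-day decline (morning sessions
are completed slightly more often than evening ones), tapping at roughly
50 strikes per 30-second trial (600 ms mean inter-tap interval), and 90%
touch accuracy.  Each patient draws an independent substream from the root
seed, so cohorts are reproducible and individually re-generable.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .fittest import KeystrokeEvent, qwerty_adjacency
from .interaction import ScreenLayout, TargetRegion, hit_test
from .protocol import (
    Protocol,
    SessionKind,
    TaskKind,
    default_protocol,
    schedule_slots,
)

__all__ = [
    "MotorParams",
    "SimParams",
    "GroundTruth",
    "default_layout",
    "tapping_stream",
    "touch_stream",
    "simulate_cohort",
]

TZ = dt.timezone(dt.timedelta(hours=1))  # fixed local offset; no DST games
_START_DATE = dt.date(2024, 3, 4)

_SESSION_ORDINAL = {
    SessionKind.ON_WAKING: 0,
    SessionKind.AFTER_MEDICATIONS: 1,
    SessionKind.AFTERNOON: 2,
    SessionKind.EVENING: 3,
}


class MotorParams(BaseModel):
    """Tapping kinematics of one (simulated) hand."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    dwell_mean_ms: float = Field(default=120.0, gt=0)
    dwell_sd_ms: float = Field(default=10.0, ge=0)
    travel_mean_ms: float = Field(default=480.0, gt=0)
    travel_sd_ms: float = Field(default=30.0, ge=0)
    error_rate: float = Field(default=0.05, ge=0, le=1)
    adjacent_error_fraction: float = Field(default=0.8, ge=0, le=1)

    @property
    def taps_per_s(self) -> float:
        return 1000.0 / (self.dwell_mean_ms + self.travel_mean_ms)


class SimParams(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int
    n_patients: int = Field(default=26, ge=1)
    home_nights: int = Field(default=14, ge=1)
    version: str = "v2.0"
    # anchor timing (hours are local clock, jitters are 1-sd minutes)
    wake_mean_h: float = 7.0
    wake_jitter_min: float = 30.0
    med_delay_mean_min: float = 45.0
    med_delay_jitter_min: float = 15.0
    afternoon_h: float = 15.0
    afternoon_jitter_min: float = 20.0
    bedtime_mean_h: float = 22.0
    bedtime_jitter_min: float = 40.0
    nap_prob: float = Field(default=0.15, ge=0, le=1)
    # adherence: per-session-kind completion probability, times a
    # multiplicative decline per within-day session ordinal
    adherence: dict[str, float] = Field(
        default_factory=lambda: {
            "on_waking": 0.92,
            "after_medications": 0.92,
            "afternoon": 0.92,
            "evening": 0.92,
        }
    )
    within_day_decline: float = Field(default=0.985, gt=0, le=1)
    # motor: cohort-level means; per-patient values are drawn around them
    motor: MotorParams = MotorParams()
    between_patient_dwell_sd: float = 15.0
    between_patient_travel_sd: float = 60.0
    # interaction & workload
    touch_accuracy: float = Field(default=0.9, ge=0, le=1)
    touches_per_session_mean: float = Field(default=40.0, ge=0)
    scales_duration_s: float = 55.0
    fit_duration_s: float = 70.0
    diary_duration_s: float = 180.0
    duration_noise_frac: float = 0.15

    def session_adherence(self, kind: SessionKind) -> float:
        base = self.adherence[kind.value]
        return min(1.0, base * self.within_day_decline ** _SESSION_ORDINAL[kind])


@dataclasses.dataclass
class GroundTruth:
    """Realized simulation state sufficient to recompute every statistic."""

    params: SimParams
    per_patient_motor: dict  # pid -> MotorParams
    adherence_draws: dict  # pid -> {(study_day, kind value): bool}
    start_date: dt.date = _START_DATE

    def expected_completed_tasks(self) -> int:
        """Brute-force completed-task count implied by the adherence draws:
        scales + tapping per adhered scheduled session, one diary per adhered
        after-medications session."""
        total = 0
        for draws in self.adherence_draws.values():
            for (_day, kind), done in draws.items():
                if not done:
                    continue
                total += 2  # subjective scales + tapping test
                if kind == SessionKind.AFTER_MEDICATIONS.value:
                    total += 1  # diary rides on the morning-medication session
        return total


def default_layout() -> ScreenLayout:
    """A plain 1280x800 question screen: four large answer buttons, a next
    button and a back button."""
    regions = [
        TargetRegion("answer_1", 140, 200, 620, 320),
        TargetRegion("answer_2", 660, 200, 1140, 320),
        TargetRegion("answer_3", 140, 360, 620, 480),
        TargetRegion("answer_4", 660, 360, 1140, 480),
        TargetRegion("back", 80, 620, 360, 740),
        TargetRegion("next", 920, 620, 1200, 740),
    ]
    return ScreenLayout(width=1280, height=800, regions=tuple(regions))


# -- low-level stream generators -------------------------------------------

_ADJACENCY = qwerty_adjacency()
_DISTANT_KEYS = ("q", "p", "z", "/")


def tapping_stream(
    motor: MotorParams,
    duration_s: float = 30.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    target_keys: tuple[str, str] = ("s", ";"),
) -> list[KeystrokeEvent]:
    """One alternating two-key tapping stream with Gaussian dwell and travel
    noise; wrong-key strikes are injected at ``error_rate``, landing on a key
    adjacent to the intended target with probability
    ``adjacent_error_fraction`` and on a distant key otherwise."""
    if rng is None:
        rng = np.random.default_rng(seed)
    horizon = duration_s * 1000.0
    events: list[KeystrokeEvent] = []
    t = max(1.0, rng.normal(motor.travel_mean_ms / 2, motor.travel_sd_ms))
    idx = 0
    while True:
        dwell = max(1.0, rng.normal(motor.dwell_mean_ms, motor.dwell_sd_ms))
        if t + dwell > horizon:
            break
        intended = target_keys[idx % 2]
        key = intended
        if rng.random() < motor.error_rate:
            if rng.random() < motor.adjacent_error_fraction:
                neighbours = sorted(_ADJACENCY.get(intended, frozenset()) - set(target_keys))
                if neighbours:
                    key = neighbours[rng.integers(len(neighbours))]
            else:
                key = _DISTANT_KEYS[rng.integers(len(_DISTANT_KEYS))]
        events.append(KeystrokeEvent(key=key, down_ms=t, up_ms=t + dwell))
        t = t + dwell + max(1.0, rng.normal(motor.travel_mean_ms, motor.travel_sd_ms))
        idx += 1
    return events


def touch_stream(
    accuracy: float,
    layout: ScreenLayout,
    n_touches: int,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    t0: float = 0.0,
) -> list[dict]:
    """``n_touches`` screen touches, each landing on a button region with
    probability ``accuracy``.  Returns raw dicts (x, y, t, on_target,
    target_id) ready for the event stream."""
    if rng is None:
        rng = np.random.default_rng(seed)
    touches = []
    t = t0
    for _ in range(n_touches):
        t += float(rng.exponential(1.5))
        if rng.random() < accuracy:
            region = layout.regions[rng.integers(len(layout.regions))]
            x = float(rng.uniform(region.x0, region.x1))
            y = float(rng.uniform(region.y0, region.y1))
        else:
            for _attempt in range(100):
                x = float(rng.uniform(0, layout.width))
                y = float(rng.uniform(0, layout.height))
                if hit_test(layout, x, y) is None:
                    break
        target = hit_test(layout, x, y)
        touches.append(
            {"x": x, "y": y, "t": t, "on_target": target is not None, "target_id": target}
        )
    return touches


# -- questionnaire answers --------------------------------------------------

def _draw_answers(protocol: Protocol, task: TaskKind, latents: dict, rng) -> dict:
    """One complete, in-domain response set; values wander around a
    per-patient latent level so longitudinal series look like trajectories
    rather than white noise."""
    answers: dict[str, object] = {}
    for q in protocol.task(task).questions:
        dom = q.domain
        if dom.kind == "int_range":
            centre = latents.setdefault(q.id, float(rng.uniform(dom.lo, dom.hi)))
            centre += float(rng.normal(0, 0.4))
            centre = min(max(centre, dom.lo), dom.hi)
            latents[q.id] = centre
            answers[q.id] = int(round(centre))
        elif dom.kind == "categorical":
            levels = list(dom.levels)
            centre = latents.setdefault(q.id, float(rng.uniform(0, len(levels) - 1)))
            centre += float(rng.normal(0, 0.3))
            centre = min(max(centre, 0.0), len(levels) - 1.0)
            latents[q.id] = centre
            answers[q.id] = levels[int(round(centre))]
        else:  # timestamp
            h = int(rng.integers(21, 24)) % 24
            m = int(rng.integers(0, 60))
            answers[q.id] = f"{h:02d}:{m:02d}"
    return answers


# -- cohort simulation ------------------------------------------------------

def _local(day: int, hours: float) -> dt.datetime:
    base = dt.datetime.combine(_START_DATE + dt.timedelta(days=day), dt.time(), TZ)
    return base + dt.timedelta(hours=hours)


def _day_kinds(day: int, home_nights: int) -> list[SessionKind]:
    if day == 0:
        return [SessionKind.EVENING]
    if day == home_nights:
        return [SessionKind.ON_WAKING, SessionKind.AFTER_MEDICATIONS]
    return [
        SessionKind.ON_WAKING,
        SessionKind.AFTER_MEDICATIONS,
        SessionKind.AFTERNOON,
        SessionKind.EVENING,
    ]


def simulate_cohort(params: SimParams) -> tuple[list[dict], GroundTruth]:
    """Generate the full event stream for a seeded cohort.

    Returns ``(events, ground_truth)`` where ``events`` is a chronological
    (per patient) list of anchor/task/touch event dicts in the documented
    stream dialect, and ``ground_truth`` carries realized per-patient motor
    parameters and every per-session adherence draw.
    """
    protocol = default_protocol(params.version, params.home_nights)  # type: ignore[arg-type]
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(params.n_patients)
    layout = default_layout()

    events: list[dict] = []
    motor_truth: dict[str, MotorParams] = {}
    adherence_truth: dict[str, dict] = {}

    for p_idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"pt{p_idx + 1:03d}"
        motor = MotorParams(
            dwell_mean_ms=max(
                40.0, float(rng.normal(params.motor.dwell_mean_ms, params.between_patient_dwell_sd))
            ),
            dwell_sd_ms=params.motor.dwell_sd_ms,
            travel_mean_ms=max(
                120.0,
                float(rng.normal(params.motor.travel_mean_ms, params.between_patient_travel_sd)),
            ),
            travel_sd_ms=params.motor.travel_sd_ms,
            error_rate=params.motor.error_rate,
            adjacent_error_fraction=params.motor.adjacent_error_fraction,
        )
        motor_truth[pid] = motor
        draws: dict[tuple[int, str], bool] = {}
        latents: dict[str, float] = {}
        diary_latents: dict[str, float] = {}

        def emit(event_type: str, payload: dict, at: dt.datetime) -> None:
            events.append(
                {
                    "patient_id": pid,
                    "event_type": event_type,
                    "payload": payload,
                    "timestamp": at.isoformat(),
                }
            )

        def duration(mean_s: float) -> float:
            lo = 1.0 - params.duration_noise_frac
            hi = 1.0 + params.duration_noise_frac
            return round(float(rng.uniform(lo, hi)) * mean_s, 1)

        def emit_session(
            kind: SessionKind, day: int, due: dt.datetime, with_diary: bool = False
        ) -> tuple[bool, dt.datetime]:
            """Adherence draw and, if adhered, a complete set of task events
            shortly after the due time.  Returns (adhered, last task time)."""
            adhered = bool(rng.random() < params.session_adherence(kind))
            draws[(day, kind.value)] = adhered
            if not adhered:
                return False, due
            now = due + dt.timedelta(minutes=float(rng.uniform(2, 12)))
            session_payload = {"session": kind.value, "study_day": day}

            answers = _draw_answers(protocol, TaskKind.SUBJECTIVE_SCALES, latents, rng)
            emit(
                "task",
                {
                    **session_payload,
                    "task_kind": "subjective_scales",
                    "answers": answers,
                    "duration_s": duration(params.scales_duration_s),
                },
                now,
            )

            hands = {
                hand: [
                    {"key": ev.key, "down_ms": ev.down_ms, "up_ms": ev.up_ms}
                    for ev in tapping_stream(motor, rng=rng)
                ]
                for hand in ("left", "right")
            }
            last = now + dt.timedelta(minutes=2)
            emit(
                "task",
                {
                    **session_payload,
                    "task_kind": "fit_test",
                    "hands": hands,
                    "duration_s": duration(params.fit_duration_s),
                },
                last,
            )

            if with_diary:
                answers = _draw_answers(protocol, TaskKind.SLEEP_DIARY, diary_latents, rng)
                last = now + dt.timedelta(minutes=4)
                emit(
                    "task",
                    {
                        **session_payload,
                        "task_kind": "sleep_diary",
                        "answers": answers,
                        "duration_s": duration(params.diary_duration_s),
                    },
                    last,
                )

            if params.touches_per_session_mean > 0 and protocol.features.interaction_logging:
                n_touches = int(rng.poisson(params.touches_per_session_mean))
                for touch in touch_stream(params.touch_accuracy, layout, n_touches, rng=rng):
                    emit(
                        "touch",
                        {**session_payload, **touch},
                        now + dt.timedelta(seconds=touch["t"]),
                    )
            return True, last

        for day in range(params.home_nights + 1):
            kinds = _day_kinds(day, params.home_nights)

            if SessionKind.ON_WAKING in kinds:
                wake = _local(day, params.wake_mean_h) + dt.timedelta(
                    minutes=float(np.clip(rng.normal(0, params.wake_jitter_min), -80, 110))
                )
                emit("anchor", {"kind": "wake_time", "study_day": day}, wake)
                adhered, last = emit_session(SessionKind.ON_WAKING, day, wake + dt.timedelta(minutes=30))
                # The first morning dose is taken only after the pre-dose
                # assessment: the medication anchor closes the on-waking window.
                med = wake + dt.timedelta(
                    minutes=max(
                        10.0,
                        float(rng.normal(params.med_delay_mean_min, params.med_delay_jitter_min)),
                    )
                )
                if adhered:
                    med = max(med, last + dt.timedelta(minutes=10))
                emit("anchor", {"kind": "first_med_intake", "study_day": day}, med)
                emit_session(
                    SessionKind.AFTER_MEDICATIONS,
                    day,
                    med + dt.timedelta(minutes=60),
                    with_diary=True,
                )

            if SessionKind.AFTERNOON in kinds:
                noon = _local(day, params.afternoon_h) + dt.timedelta(
                    minutes=float(np.clip(rng.normal(0, params.afternoon_jitter_min), -80, 80))
                )
                if rng.random() < params.nap_prob:
                    nap_end = noon - dt.timedelta(minutes=float(rng.uniform(40, 90)))
                    emit("anchor", {"kind": "nap_end", "study_day": day}, nap_end)
                emit("anchor", {"kind": "pre_afternoon_dose", "study_day": day}, noon)
                emit_session(SessionKind.AFTERNOON, day, noon)

            if SessionKind.EVENING in kinds:
                bed = _local(day, params.bedtime_mean_h) + dt.timedelta(
                    minutes=float(np.clip(rng.normal(0, params.bedtime_jitter_min), -85, 100))
                )
                emit("anchor", {"kind": "bedtime", "study_day": day}, bed)
                emit_session(SessionKind.EVENING, day, bed)

        adherence_truth[pid] = draws

    truth = GroundTruth(
        params=params, per_patient_motor=motor_truth, adherence_draws=adherence_truth
    )
    return events, truth
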