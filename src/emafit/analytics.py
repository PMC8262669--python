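"""Compliance, version comparison, satisfaction and workload analytics.

Compliance is the percentage of protocol-expected tasks actually completed
over the home analysis window (the arrival evening through the final
morning's after-medications session); on-demand nap sessions are excluded
because they cannot be scheduled a priori, and a missing task counts as
non-compliant regardless of cause.  Version improvements are assessed with
a classical one-tailed two-sample proportion z-test (pooled variance).

All printed percentages go through the centralized half-up rounding rules:
two decimals for compliance, whole percents for satisfaction tallies.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .protocol import (
    Protocol,
    SessionKind,
    TaskKind,
    diary_days,
    expected_tasks,
    schedule_slots,
)
from .rounding import percent, round_half_up
from .store import Record

__all__ = [
    "ComplianceCell",
    "ComplianceReport",
    "SatisfactionSummary",
    "compliance",
    "compliance_report",
    "compare_proportions",
    "satisfaction_summary",
    "workload_summary",
]

_RECORD_TYPE_TO_TASK = {
    "scales": TaskKind.SUBJECTIVE_SCALES,
    "fit_test": TaskKind.FIT_TEST,
    "sleep_diary": TaskKind.SLEEP_DIARY,
}


def compliance(completed: int, expected: int) -> float:
    """Compliance percentage, half-up to 2 decimals.

    ``compliance(5707, 6420) == 88.89``.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if not 0 <= completed <= expected:
        raise ValueError("completed must lie in [0, expected]")
    return percent(completed, expected, ndigits=2)


@dataclasses.dataclass(frozen=True)
class ComplianceCell:
    completed: int
    expected: int

    @property
    def percent(self) -> Optional[float]:
        return compliance(self.completed, self.expected) if self.expected else None


@dataclasses.dataclass(frozen=True)
class ComplianceReport:
    completed: int
    expected: int
    breakdown: dict  # (version, session kind value | "any", task kind value) -> ComplianceCell

    @property
    def percent(self) -> float:
        return compliance(self.completed, self.expected)

    def cell(self, version: str, session: Optional[str], task: str) -> ComplianceCell:
        return self.breakdown[(version, session or "any", task)]

    def version_totals(self) -> dict[str, ComplianceCell]:
        out: dict[str, list[int]] = {}
        for (version, _s, _t), c in self.breakdown.items():
            agg = out.setdefault(version, [0, 0])
            agg[0] += c.completed
            agg[1] += c.expected
        return {v: ComplianceCell(*agg) for v, agg in out.items()}


def _is_home_task_record(record: Record) -> bool:
    return record.categorization == "H" and record.record_type in _RECORD_TYPE_TO_TASK


def compliance_report(
    records: Iterable[Record],
    protocols: Mapping[str, Protocol],
    cohort: Mapping[str, str],
) -> ComplianceReport:
    """Completed/expected accounting by version x session x task.

    ``cohort`` assigns each patient to the application version they used;
    expected counts come from that version's workload ledger.  A completed
    task is a stored home (``H``) record whose ``(study_day, session)`` falls
    inside the analysis window; duplicates of the same slot are counted once.
    The once-daily diary is keyed by study day only and reported under the
    pseudo-session ``"any"``.
    """
    breakdown: dict[tuple, list[int]] = {}
    slot_sets: dict[str, set] = {}
    diary_sets: dict[str, set] = {}
    for version, proto in protocols.items():
        slot_sets[version] = {(d, k.value) for d, k in schedule_slots(proto)}
        diary_sets[version] = set(diary_days(proto))
        for day, kind in schedule_slots(proto):
            for task in proto.session(kind).tasks:
                if proto.task(task).frequency != "per_session":
                    continue
                key = (version, kind.value, task.value)
                breakdown.setdefault(key, [0, 0])
        breakdown.setdefault((version, "any", TaskKind.SLEEP_DIARY.value), [0, 0])

    # expected = per-slot counts x number of patients on that version
    patients_per_version: dict[str, int] = {}
    for _pid, version in cohort.items():
        patients_per_version[version] = patients_per_version.get(version, 0) + 1
    for version, n_patients in patients_per_version.items():
        proto = protocols[version]
        for day, kind in schedule_slots(proto):
            for task in proto.session(kind).tasks:
                if proto.task(task).frequency != "per_session":
                    continue
                breakdown[(version, kind.value, task.value)][1] += n_patients
        breakdown[(version, "any", TaskKind.SLEEP_DIARY.value)][1] += n_patients * len(
            diary_sets[version]
        )

    seen: set[tuple] = set()
    for record in records:
        if not _is_home_task_record(record):
            continue
        version = cohort.get(record.patient_id)
        if version is None:
            continue
        task = _RECORD_TYPE_TO_TASK[record.record_type]
        day = record.payload.get("study_day")
        if day is None:
            continue
        if task is TaskKind.SLEEP_DIARY:
            if day not in diary_sets[version]:
                continue
            dedup = (record.patient_id, day, task.value)
            key = (version, "any", task.value)
        else:
            if (day, record.session) not in slot_sets[version]:
                continue
            dedup = (record.patient_id, day, record.session, task.value)
            key = (version, record.session, task.value)
        if dedup in seen:
            continue
        seen.add(dedup)
        breakdown[key][0] += 1

    cells = {k: ComplianceCell(*v) for k, v in breakdown.items()}
    total_done = sum(c.completed for c in cells.values())
    total_exp = sum(c.expected for c in cells.values())
    return ComplianceReport(completed=total_done, expected=total_exp, breakdown=cells)


def compare_proportions(
    done_a: int, total_a: int, done_b: int, total_b: int
) -> dict[str, float]:
    """Classical one-tailed two-sample proportion test, pooled variance,
    without continuity correction; alternative: proportion B > proportion A.

    Returns the raw statistic and p-value plus 4-decimal rounded copies.
    A Yates-corrected variant is available via :func:`compare_proportions_yates`.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    p_a, p_b = done_a / total_a, done_b / total_b
    pooled = (done_a + done_b) / (total_a + total_b)
    se = math.sqrt(pooled * (1 - pooled) * (1 / total_a + 1 / total_b))
    z = (p_b - p_a) / se
    p_one = float(stats.norm.sf(z))
    return {
        "z": z,
        "p_one_tailed": p_one,
        "z_4dp": round_half_up(z, 4),
        "p_4dp": round_half_up(p_one, 4),
    }


def compare_proportions_yates(
    done_a: int, total_a: int, done_b: int, total_b: int
) -> dict[str, float]:
    """Continuity-corrected variant of :func:`compare_proportions`."""
    p_a, p_b = done_a / total_a, done_b / total_b
    pooled = (done_a + done_b) / (total_a + total_b)
    se = math.sqrt(pooled * (1 - pooled) * (1 / total_a + 1 / total_b))
    correction = 0.5 * (1 / total_a + 1 / total_b)
    diff = p_b - p_a
    z = (abs(diff) - correction) / se * (1 if diff >= 0 else -1)
    p_one = float(stats.norm.sf(z))
    return {
        "z": z,
        "p_one_tailed": p_one,
        "z_4dp": round_half_up(z, 4),
        "p_4dp": round_half_up(p_one, 4),
    }


@dataclasses.dataclass(frozen=True)
class SatisfactionSummary:
    """Per-question tallies of categorical satisfaction answers (levels 1-4,
    1 = low satisfaction, 4 = high)."""

    counts: dict  # question id -> {level: count}

    def respondents(self, question: str) -> int:
        return sum(self.counts[question].values())

    def percent(self, question: str, levels: Sequence[int]) -> int:
        """Whole-percent (half-up) share of respondents at the given levels."""
        n = self.respondents(question)
        hit = sum(self.counts[question].get(lv, 0) for lv in levels)
        return int(percent(hit, n, ndigits=0))

    def pooled_percent(self, questions: Sequence[str], levels: Sequence[int]) -> int:
        """Share over answers pooled across questions — e.g. the three
        usability questions pooled over respondents x 3 answers."""
        n = sum(self.respondents(q) for q in questions)
        hit = sum(
            self.counts[q].get(lv, 0) for q in questions for lv in levels
        )
        return int(percent(hit, n, ndigits=0))


def satisfaction_summary(
    responses: Mapping[str, Sequence[int]]
) -> SatisfactionSummary:
    """Tally one categorical answer (1-4) per respondent per question."""
    counts: dict[str, dict[int, int]] = {}
    for question, answers in responses.items():
        tally: dict[int, int] = {}
        for a in answers:
            if a not in (1, 2, 3, 4):
                raise ValueError(f"satisfaction level {a!r} outside 1-4")
            tally[a] = tally.get(a, 0) + 1
        counts[question] = tally
    return SatisfactionSummary(counts=counts)


def workload_summary(records: Iterable[Record]) -> dict:
    """Mean daily active minutes per patient and their cohort mean.

    Task records carry a ``duration_s`` payload; durations are summed per
    patient per study day, averaged over that patient's active days, then
    averaged over patients.  Returns ``{"per_patient": {pid: seconds},
    "cohort_mean_s": seconds | None}``.
    """
    per_day: dict[tuple[str, int], float] = {}
    for record in records:
        if not _is_home_task_record(record):
            continue
        duration = record.payload.get("duration_s")
        day = record.payload.get("study_day")
        if duration is None or day is None:
            continue
        key = (record.patient_id, day)
        per_day[key] = per_day.get(key, 0.0) + float(duration)

    by_patient: dict[str, list[float]] = {}
    for (pid, _day), total in per_day.items():
        by_patient.setdefault(pid, []).append(total)
    per_patient = {
        pid: math.fsum(days) / len(days) for pid, days in sorted(by_patient.items())
    }
    cohort = (
        math.fsum(per_patient.values()) / len(per_patient) if per_patient else None
    )
    return {"per_patient": per_patient, "cohort_mean_s": cohort}
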