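"""Touch-log usability analytics: the target ratio.

From v1.0 on, the application logs every touchscreen interaction (x, y,
timestamp) whether or not it lands on a button.  The *target ratio* of a
session is the percentage of touches that hit an active button region; a
cohort value is obtained by averaging per-session ratios within each patient
over the included sessions, then averaging the per-patient means without
weighting — never by pooling raw touches across patients.

Sessions included in the cohort average are the fully completed home days
only: the arrival evening (day 0) and the final morning's two sessions are
excluded, removing exactly three of the 4n - 1 scheduled slots of an n-night
home period.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Optional, Sequence

from .protocol import Protocol, SessionKind, schedule_slots

__all__ = [
    "TargetRegion",
    "ScreenLayout",
    "InteractionEvent",
    "TargetRatio",
    "hit_test",
    "target_ratio",
    "included_sessions",
    "average_target_ratio",
]


@dataclasses.dataclass(frozen=True)
class TargetRegion:
    """Half-open button rectangle [x0, x1) x [y0, y1) in screen pixels."""

    target_id: str
    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclasses.dataclass(frozen=True)
class ScreenLayout:
    width: int
    height: int
    regions: tuple[TargetRegion, ...]

    def __post_init__(self) -> None:
        for r in self.regions:
            if not (0 <= r.x0 < r.x1 <= self.width and 0 <= r.y0 < r.y1 <= self.height):
                raise ValueError(f"region {r.target_id} outside screen bounds")


@dataclasses.dataclass(frozen=True)
class InteractionEvent:
    x: float
    y: float
    timestamp: float
    on_target: bool
    target_id: Optional[str] = None
    session: Optional[tuple[int, str]] = None  # (study_day, session kind value)


@dataclasses.dataclass(frozen=True)
class TargetRatio:
    hits: int
    touches: int

    @property
    def ratio(self) -> float:
        """Percent of touches on target; undefined for an empty log."""
        if self.touches == 0:
            raise ZeroDivisionError("target ratio of an empty touch log")
        return 100.0 * self.hits / self.touches


def hit_test(layout: ScreenLayout, x: float, y: float) -> Optional[str]:
    """Target under (x, y), or None.  Overlapping regions resolve to the
    earliest-declared one; rectangle edges follow the half-open convention."""
    if not (0 <= x <= layout.width and 0 <= y <= layout.height):
        raise ValueError("coordinates outside screen")
    for region in layout.regions:
        if region.contains(x, y):
            return region.target_id
    return None


def target_ratio(events: Sequence[InteractionEvent]) -> TargetRatio:
    """Hits over touches for one event log.  Every event is a touch."""
    hits = sum(1 for ev in events if ev.on_target)
    return TargetRatio(hits=hits, touches=len(events))


def included_sessions(protocol: Protocol) -> set[tuple[int, SessionKind]]:
    """Scheduled slots entering the cohort target-ratio average: all slots of
    fully completed days, i.e. everything except the day-0 evening and the
    final morning's on-waking and after-medications sessions."""
    n = protocol.home_nights
    excluded = {
        (0, SessionKind.EVENING),
        (n, SessionKind.ON_WAKING),
        (n, SessionKind.AFTER_MEDICATIONS),
    }
    return {slot for slot in schedule_slots(protocol) if slot not in excluded}


def average_target_ratio(
    patient_logs: Mapping[str, Iterable[InteractionEvent]],
    protocol: Protocol,
) -> tuple[dict[str, float], Optional[float]]:
    """Per-patient mean session ratios and their unweighted cohort mean.

    Events are grouped by their session reference; sessions outside
    :func:`included_sessions` and zero-touch sessions contribute nothing.
    A patient with no usable session is excluded from the cohort mean; the
    cohort mean is None when no patient remains.
    """
    included = {(day, kind.value) for day, kind in included_sessions(protocol)}
    per_patient: dict[str, float] = {}
    for patient, events in patient_logs.items():
        by_session: dict[tuple[int, str], list[InteractionEvent]] = {}
        for ev in events:
            if ev.session is None or ev.session not in included:
                continue
            by_session.setdefault(ev.session, []).append(ev)
        ratios = [
            target_ratio(evs).ratio for evs in by_session.values() if evs
        ]
        if ratios:
            per_patient[patient] = math.fsum(ratios) / len(ratios)
    cohort = (
        math.fsum(per_patient.values()) / len(per_patient) if per_patient else None
    )
    return per_patient, cohort
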