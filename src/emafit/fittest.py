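"""Scoring of the 30-second alternating two-key tapping trial.

The motor task asks the patient to strike two physical keys about 10 cm
apart, alternately, for 30 seconds with one hand at a time.  Four kinematic
parameters summarise each trial:

* **kinesia score (KS)** — number of keystrokes in the window (tapping speed);
* **akinesia time (AT)** — mean key dwell time in ms (hold hesitation);
* **incoordination score (IS)** — sample variance (n-1 denominator) of the
  travel times between consecutive keystrokes, in ms^2 (rhythm irregularity);
* **dysmetria score (DS)** — accuracy-weighted rate of incorrect strikes
  (weight 0 for a target key, 1 for a key adjacent to a target, 2 otherwise),
  normalised by the keystroke count.

Travel time is measured key-up -> next key-down by default (``down_down``
is available as an option).  Incorrect strikes count toward KS — they are
keystrokes — but are excluded from the dwell and travel statistics by
default, so a stray hit does not contaminate the timing estimates.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import statistics
from typing import Literal, Optional, Sequence

__all__ = [
    "KeystrokeEvent",
    "FitTestTrial",
    "FitTestResult",
    "TrialRejected",
    "UndefinedScore",
    "qwerty_adjacency",
    "validate_trial",
    "kinesia_score",
    "akinesia_time",
    "incoordination_score",
    "dysmetria_score",
    "score_trial",
]

TRIAL_DURATION_S = 30.0


class TrialRejected(ValueError):
    """The trial failed validation and produces no stored result."""


class UndefinedScore(ValueError):
    """Too few keystrokes to define the requested statistic."""


@dataclasses.dataclass(frozen=True)
class KeystrokeEvent:
    key: str
    down_ms: float
    up_ms: float


@dataclasses.dataclass(frozen=True)
class FitTestTrial:
    hand: Literal["left", "right"]
    target_keys: tuple[str, str]
    events: tuple[KeystrokeEvent, ...]
    duration_s: float = TRIAL_DURATION_S

    def __post_init__(self) -> None:
        if self.target_keys[0] == self.target_keys[1]:
            raise ValueError("target keys must be distinct")


@dataclasses.dataclass(frozen=True)
class FitTestResult:
    hand: str
    kinesia_score: int
    akinesia_time_ms: float
    incoordination_score_ms2: float
    dysmetria_score: float
    timestamp: Optional[dt.datetime] = None

    def as_row(self) -> dict:
        return {
            "hand": self.hand,
            "KS": self.kinesia_score,
            "AT": self.akinesia_time_ms,
            "IS": self.incoordination_score_ms2,
            "DS": self.dysmetria_score,
        }


# -- keyboard geometry ------------------------------------------------------

_QWERTY_ROWS = ("1234567890", "qwertyuiop", "asdfghjkl;", "zxcvbnm,./")


def qwerty_adjacency() -> dict[str, frozenset[str]]:
    """Adjacency map of a plain QWERTY grid: neighbours are the keys at
    column offset <= 1 on the same or a neighbouring row."""
    pos = {
        key: (r, c)
        for r, row in enumerate(_QWERTY_ROWS)
        for c, key in enumerate(row)
    }
    adj: dict[str, set[str]] = {k: set() for k in pos}
    for a, (ra, ca) in pos.items():
        for b, (rb, cb) in pos.items():
            if a != b and abs(ra - rb) <= 1 and abs(ca - cb) <= 1:
                adj[a].add(b)
    return {k: frozenset(v) for k, v in adj.items()}


_DEFAULT_ADJACENCY = qwerty_adjacency()


# -- validation -------------------------------------------------------------

def validate_trial(trial: FitTestTrial) -> tuple[bool, Optional[str]]:
    """Accept a trial iff every event lies inside the 30-second window, holds
    do not overlap, timestamps are ordered, and at least one keystroke exists."""
    if not trial.events:
        return False, "no keystrokes"
    horizon = trial.duration_s * 1000.0
    prev_down = -float("inf")
    prev_up = -float("inf")
    for ev in trial.events:
        if ev.up_ms < ev.down_ms:
            return False, "key release precedes key press"
        if ev.down_ms < 0 or ev.up_ms > horizon:
            return False, "outside window"
        if ev.down_ms < prev_down:
            return False, "events out of order"
        if ev.down_ms < prev_up:
            return False, "overlapping key-holds"
        prev_down, prev_up = ev.down_ms, ev.up_ms
    return True, None


def _require_valid(trial: FitTestTrial) -> None:
    ok, reason = validate_trial(trial)
    if not ok:
        raise TrialRejected(reason)


def _timing_events(
    trial: FitTestTrial, include_errors: bool
) -> Sequence[KeystrokeEvent]:
    if include_errors:
        return trial.events
    targets = set(trial.target_keys)
    return [ev for ev in trial.events if ev.key in targets]


# -- the four parameters ----------------------------------------------------

def kinesia_score(trial: FitTestTrial) -> int:
    """Number of key-down events during the window, on any key."""
    _require_valid(trial)
    return len(trial.events)


def akinesia_time(trial: FitTestTrial, *, include_errors: bool = False) -> float:
    """Arithmetic mean dwell (up - down) in ms over the scored keystrokes."""
    _require_valid(trial)
    events = _timing_events(trial, include_errors)
    if not events:
        raise UndefinedScore("no target keystrokes to time")
    return statistics.fmean(ev.up_ms - ev.down_ms for ev in events)


def travel_times(
    trial: FitTestTrial,
    *,
    include_errors: bool = False,
    travel: Literal["up_down", "down_down"] = "up_down",
) -> list[float]:
    """Inter-keystroke travel times in ms between consecutive scored strikes."""
    _require_valid(trial)
    events = _timing_events(trial, include_errors)
    if travel == "up_down":
        return [b.down_ms - a.up_ms for a, b in zip(events, events[1:])]
    return [b.down_ms - a.down_ms for a, b in zip(events, events[1:])]


def incoordination_score(
    trial: FitTestTrial,
    *,
    include_errors: bool = False,
    travel: Literal["up_down", "down_down"] = "up_down",
) -> float:
    """Sample variance (ddof=1) of the travel times, in ms^2."""
    ts = travel_times(trial, include_errors=include_errors, travel=travel)
    if len(ts) < 2:
        raise UndefinedScore("incoordination needs at least 3 keystrokes")
    return statistics.variance(ts)


def dysmetria_score(
    trial: FitTestTrial,
    adjacency: Optional[dict[str, frozenset[str]]] = None,
) -> float:
    """Accuracy-weighted miss rate: mean strike weight over all keystrokes,
    where a target key weighs 0, a key adjacent to either target 1, and any
    other key 2.  All-on-target trials score 0; the maximum is 2."""
    _require_valid(trial)
    adjacency = _DEFAULT_ADJACENCY if adjacency is None else adjacency
    targets = set(trial.target_keys)
    near = set().union(*(adjacency.get(t, frozenset()) for t in targets)) - targets
    total = 0
    for ev in trial.events:
        if ev.key in targets:
            continue
        total += 1 if ev.key in near else 2
    return total / len(trial.events)


def score_trial(
    trial: FitTestTrial,
    *,
    include_errors: bool = False,
    travel: Literal["up_down", "down_down"] = "up_down",
    adjacency: Optional[dict[str, frozenset[str]]] = None,
    timestamp: Optional[dt.datetime] = None,
) -> FitTestResult:
    """Bundle the four parameters for one validated trial.

    Deterministic for a fixed input; a rejected trial raises
    :class:`TrialRejected` and nothing is stored.
    """
    _require_valid(trial)
    return FitTestResult(
        hand=trial.hand,
        kinesia_score=kinesia_score(trial),
        akinesia_time_ms=akinesia_time(trial, include_errors=include_errors),
        incoordination_score_ms2=incoordination_score(
            trial, include_errors=include_errors, travel=travel
        ),
        dysmetria_score=dysmetria_score(trial, adjacency),
        timestamp=timestamp,
    )
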