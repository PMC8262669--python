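"""Newline-delimited JSON event-stream files.

One event per line: ``{"patient_id": ..., "event_type": "anchor" | "task" |
"touch", "payload": {...}, "timestamp": ISO-8601 with offset}``.  Keys are
written sorted so a write/read/write cycle is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

REQUIRED_FIELDS = ("patient_id", "event_type", "payload", "timestamp")
EVENT_TYPES = ("anchor", "task", "touch")


def validate_event(event: dict) -> dict:
    for field in REQUIRED_FIELDS:
        if field not in event:
            raise ValueError(f"event missing field {field!r}")
    if event["event_type"] not in EVENT_TYPES:
        raise ValueError(f"unknown event_type {event['event_type']!r}")
    return event


def write_stream(path, events: Iterable[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for event in events:
            fh.write(json.dumps(validate_event(event), sort_keys=True) + "\n")


def read_stream(path) -> list[dict]:
    events = []
    with open(Path(path), "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                events.append(validate_event(json.loads(line)))
    return events


def by_patient(events: Iterable[dict]) -> dict[str, list[dict]]:
    """Group events per patient, chronologically (stable on ties, so the
    emission order of simultaneous events is preserved)."""
    grouped: dict[str, list[dict]] = {}
    for event in events:
        grouped.setdefault(event["patient_id"], []).append(event)
    return {
        pid: sorted(evs, key=lambda e: e["timestamp"])
        for pid, evs in sorted(grouped.items())
    }
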