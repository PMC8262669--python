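"""Store-and-forward persistence and portal-style retrieval.

Writes go first to an append-only local :class:`Journal` (durable even with
no connectivity), then an idempotent :func:`sync` pushes unacknowledged
records to a :class:`RemoteStore` in order, at-least-once, deduplicated by
``record_id``.  A transport failure mid-batch leaves the journal's
high-water mark at the last acknowledged record, so the next sync resumes
exactly where the previous one stopped.

Retrieval mirrors a researcher portal: conjunctive filters on patient, date
range, session, record type, tapping hand and data categorization
(H = collected at home, V0 = initial visit, V1 = follow-up visit), plus CSV
export that round-trips losslessly through :func:`import_csv`.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from .protocol import SessionKind

__all__ = [
    "Record",
    "Journal",
    "RemoteStore",
    "TransportError",
    "FlakyTransport",
    "SyncReport",
    "append",
    "sync",
    "filter_records",
    "export_csv",
    "import_csv",
]

RECORD_TYPES = ("scales", "fit_test", "sleep_diary", "anchor", "interaction")
CATEGORIZATIONS = ("H", "V0", "V1")


@dataclasses.dataclass(frozen=True)
class Record:
    record_id: str
    patient_id: str
    record_type: str
    session: Optional[str]  # session kind value, None for visit records
    date: str  # ISO calendar date
    categorization: str  # H / V0 / V1
    payload: dict
    created_at: str  # ISO-8601 timestamp

    def __post_init__(self) -> None:
        if self.record_type not in RECORD_TYPES:
            raise ValueError(f"unknown record_type {self.record_type!r}")
        if self.categorization not in CATEGORIZATIONS:
            raise ValueError(f"categorization must be one of {CATEGORIZATIONS}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "Record":
        return cls(**data)


class Journal:
    """Append-only local record log with an optional file backing.

    The file backing is newline-delimited JSON; a journal reloaded from its
    file reproduces the in-memory sequence exactly, and replaying it into an
    empty remote store reproduces the remote state.
    """

    def __init__(self, path: Optional[Path] = None) -> None:
        self.path = Path(path) if path is not None else None
        self.records: list[Record] = []
        self._ids: set[str] = set()
        self.high_water = 0  # records [0, high_water) acknowledged by remote
        if self.path is not None and self.path.exists():
            with open(self.path, "r", encoding="utf-8") as fh:
                for line in fh:
                    if line.strip():
                        rec = Record.from_dict(json.loads(line))
                        self.records.append(rec)
                        self._ids.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def unsynced(self) -> list[Record]:
        return self.records[self.high_water:]

    def synced_flags(self) -> list[bool]:
        return [i < self.high_water for i in range(len(self.records))]


def append(journal: Journal, record: Record) -> Journal:
    """Durably append one record; duplicate record ids are rejected."""
    if record.record_id in journal._ids:
        raise ValueError(f"duplicate record_id {record.record_id}")
    if journal.path is not None:
        with open(journal.path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(record.to_dict(), sort_keys=True) + "\n")
            fh.flush()
    journal.records.append(record)
    journal._ids.add(record.record_id)
    return journal


class RemoteStore:
    """In-process stand-in for the remote database: deduplicating receiver
    keyed by record_id."""

    def __init__(self) -> None:
        self._by_id: dict[str, Record] = {}

    def receive(self, record: Record) -> bool:
        """Store the record; return True iff it was new."""
        if record.record_id in self._by_id:
            return False
        self._by_id[record.record_id] = record
        return True

    @property
    def records(self) -> list[Record]:
        return list(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)


class TransportError(RuntimeError):
    """Simulated network failure between journal and remote."""


class FlakyTransport:
    """Delivers records to a remote, failing after ``fail_after`` deliveries
    (None = never).  Used to exercise retry safety."""

    def __init__(self, remote: RemoteStore, fail_after: Optional[int] = None) -> None:
        self.remote = remote
        self.fail_after = fail_after
        self.delivered = 0

    def deliver(self, record: Record) -> bool:
        if self.fail_after is not None and self.delivered >= self.fail_after:
            raise TransportError("connection lost")
        accepted = self.remote.receive(record)
        self.delivered += 1
        return accepted


@dataclasses.dataclass(frozen=True)
class SyncReport:
    pushed: int
    skipped: int
    error: Optional[str] = None


def sync(
    journal: Journal,
    remote: RemoteStore,
    transport: Optional[FlakyTransport] = None,
) -> SyncReport:
    """Push unacknowledged records in journal order, at-least-once.

    Each record is acknowledged individually; on a transport failure the
    high-water mark stays at the last acknowledged record and the error is
    reported, so a repeated sync pushes exactly the remainder.  Re-delivered
    records (possible after a failure between delivery and acknowledgment)
    are deduplicated by the remote and counted as skipped.
    """
    transport = transport or FlakyTransport(remote)
    pushed = skipped = 0
    for record in journal.unsynced():
        try:
            accepted = transport.deliver(record)
        except TransportError as exc:
            return SyncReport(pushed=pushed, skipped=skipped, error=str(exc))
        if accepted:
            pushed += 1
        else:
            skipped += 1
        journal.high_water += 1
    return SyncReport(pushed=pushed, skipped=skipped)


# -- portal-style retrieval -------------------------------------------------

_SESSION_ORDER = {k.value: k.order for k in SessionKind}


def _canonical_key(record: Record):
    return (
        record.patient_id,
        record.date,
        _SESSION_ORDER.get(record.session or "", 99),
        record.created_at,
        record.record_id,
    )


def filter_records(
    records: Iterable[Record],
    *,
    patient: Optional[str] = None,
    date_from: Optional[str] = None,
    date_to: Optional[str] = None,
    session: Optional[str] = None,
    record_type: Optional[str] = None,
    hand: Optional[str] = None,
    categorization: Optional[str] = None,
) -> list[Record]:
    """Conjunctive filtering with a deterministic canonical order
    (patient, date, session kind, created_at).  Date bounds are inclusive."""
    if record_type is not None and record_type not in RECORD_TYPES:
        raise ValueError(f"unknown record_type {record_type!r}")
    if categorization is not None and categorization not in CATEGORIZATIONS:
        raise ValueError(f"unknown categorization {categorization!r}")

    checks: list[Callable[[Record], bool]] = []
    if patient is not None:
        checks.append(lambda r: r.patient_id == patient)
    if date_from is not None:
        checks.append(lambda r: r.date >= date_from)
    if date_to is not None:
        checks.append(lambda r: r.date <= date_to)
    if session is not None:
        checks.append(lambda r: r.session == session)
    if record_type is not None:
        checks.append(lambda r: r.record_type == record_type)
    if hand is not None:
        checks.append(lambda r: r.payload.get("hand") == hand)
    if categorization is not None:
        checks.append(lambda r: r.categorization == categorization)

    kept = [r for r in records if all(c(r) for c in checks)]
    return sorted(kept, key=_canonical_key)


# -- CSV export / import ----------------------------------------------------

_BASE_COLS = (
    "record_id",
    "patient_id",
    "record_type",
    "session",
    "date",
    "categorization",
    "created_at",
)
_FIT_COLS = ("hand", "KS", "AT", "IS", "DS")


def _format_number(value) -> str:
    return repr(value) if isinstance(value, float) else str(value)


def export_csv(records: Sequence[Record], destination) -> None:
    """Write records of one type as RFC-4180-style CSV (header row, comma
    delimiter, double-quote escaping, UTF-8, ISO-8601 timestamps).

    Tapping results get dedicated hand/KS/AT/IS/DS columns; other payloads
    are carried as a canonical JSON column so re-import is lossless.
    """
    types = {r.record_type for r in records}
    if len(types) > 1:
        raise ValueError(f"records must share one record_type, got {sorted(types)}")
    record_type = next(iter(types)) if types else None

    def rows():
        if record_type == "fit_test":
            header = _BASE_COLS + _FIT_COLS + ("extra",)
            yield header
            for r in records:
                extra = {k: v for k, v in r.payload.items() if k not in _FIT_COLS}
                yield tuple(
                    [getattr(r, c) or "" for c in _BASE_COLS]
                    + [_format_number(r.payload.get(c, "")) for c in _FIT_COLS]
                    + [json.dumps(extra, sort_keys=True) if extra else ""]
                )
        else:
            yield _BASE_COLS + ("payload",)
            for r in records:
                yield tuple(
                    [getattr(r, c) or "" for c in _BASE_COLS]
                    + [json.dumps(r.payload, sort_keys=True)]
                )

    def _write(fh) -> None:
        writer = csv.writer(fh)
        for row in rows():
            writer.writerow(row)

    if hasattr(destination, "write"):
        _write(destination)
    else:
        with open(destination, "w", encoding="utf-8", newline="") as fh:
            _write(fh)


def import_csv(source) -> list[Record]:
    """Reconstruct records from an :func:`export_csv` file; a re-export of
    the result is byte-identical to the original file."""
    if hasattr(source, "read"):
        reader = csv.reader(source)
        rows = list(reader)
    else:
        with open(source, "r", encoding="utf-8", newline="") as fh:
            rows = list(csv.reader(fh))
    if not rows:
        return []
    header = rows[0]
    records = []
    for row in rows[1:]:
        data = dict(zip(header, row))
        base = {c: (data[c] or None) if c == "session" else data[c] for c in _BASE_COLS}
        if "payload" in data:
            payload = json.loads(data["payload"]) if data["payload"] else {}
        else:
            payload = {}
            if data.get("hand"):
                payload["hand"] = data["hand"]
            if data.get("KS"):
                payload["KS"] = int(data["KS"])
            for col in ("AT", "IS", "DS"):
                if data.get(col):
                    payload[col] = float(data[col])
            if data.get("extra"):
                payload.update(json.loads(data["extra"]))
        records.append(Record(payload=payload, **base))
    return records


def export_csv_string(records: Sequence[Record]) -> str:
    buf = io.StringIO(newline="")
    export_csv(records, buf)
    return buf.getvalue()
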