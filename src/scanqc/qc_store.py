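"""Durable CSV persistence of QC decisions.

Each (dataset, pipeline) pair owns one audit CSV in the QC archive, one row
per pipeline output, keyed by the full BIDS identifier tuple.  Rows carry the
three-state status (``yes`` / ``maybe`` / ``no``), the reporting user, a UTC
ISO-8601 timestamp and a free-text note.  All outputs start as ``yes``
(most outputs are expected to be good, so only problems cost a click), and
every status change is pushed to disk immediately via an atomic
write-to-temporary-then-rename so concurrent readers never observe a torn
file.  Tables from many datasets and pipelines aggregate into a single CSV
with last-write-wins conflict resolution on the timestamp.

Dialect: UTF-8, comma-separated, header
``dataset,pipeline,subject,session,acquisition,run,item,qc_status,user,timestamp,reason``,
RFC-4180 quoting.  Rows are kept sorted by full key, so a write → read →
write cycle is byte-identical.
"""

from __future__ import annotations

import csv
import os
import tempfile
from dataclasses import dataclass, replace
from datetime import datetime, timezone
from typing import Iterable, Optional, Sequence

from .bids_index import FailureReport, ScanIdentifier

__all__ = [
    "QCRecord",
    "QCTable",
    "STATUSES",
    "CSV_COLUMNS",
    "init_table",
    "load_table",
    "upsert",
    "merge_tables",
    "ingest_failures",
    "utc_now",
]

STATUSES = ("yes", "maybe", "no")

CSV_COLUMNS = ("dataset", "pipeline", "subject", "session", "acquisition",
               "run", "item", "qc_status", "user", "timestamp", "reason")

#: grace allowed when validating "timestamp not in the future" (clock skew)
_FUTURE_SLACK_S = 60.0


def utc_now() -> str:
    """Current time as an ISO-8601 UTC string with second precision."""
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%S+00:00")


def _validate_timestamp(ts: str) -> None:
    try:
        parsed = datetime.fromisoformat(ts)
    except ValueError as exc:
        raise ValueError(f"timestamp does not parse as ISO-8601: {ts!r}") from exc
    if parsed.tzinfo is None:
        parsed = parsed.replace(tzinfo=timezone.utc)
    now = datetime.now(timezone.utc)
    if (parsed - now).total_seconds() > _FUTURE_SLACK_S:
        raise ValueError(f"timestamp is in the future: {ts!r}")


@dataclass(frozen=True)
class QCRecord:
    """One row of the QC audit: who judged which output, when, and how."""

    identifier: ScanIdentifier
    status: str
    user: str
    timestamp: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(
                f"status must be one of {STATUSES}, got {self.status!r}")
        _validate_timestamp(self.timestamp)

    def row(self) -> list[str]:
        i = self.identifier
        return [i.dataset, i.pipeline, i.subject, i.session, i.acquisition,
                i.run, i.item, self.status, self.user, self.timestamp, self.note]


class QCTable:
    """In-memory view of one audit CSV, keyed by identifier tuple.

    Mutation goes through :func:`upsert` / :func:`ingest_failures`, each of
    which rewrites the backing file atomically before returning.
    """

    def __init__(self, path: Optional[str], records: Iterable[QCRecord] = ()):
        self.path = path
        self._rows: dict[tuple[str, ...], QCRecord] = {}
        for rec in records:
            key = rec.identifier.key
            if key in self._rows:
                raise ValueError(f"duplicate identifier: {key}")
            self._rows[key] = rec

    def __len__(self) -> int:
        return len(self._rows)

    def __contains__(self, ident: ScanIdentifier) -> bool:
        return ident.key in self._rows

    def get(self, ident: ScanIdentifier) -> QCRecord:
        return self._rows[ident.key]

    def records(self) -> list[QCRecord]:
        """All rows in deterministic full-key order."""
        return [self._rows[k] for k in sorted(self._rows)]

    def save(self) -> None:
        if self.path is None:
            return
        _atomic_write_csv(self.path, self.records())


def _atomic_write_csv(path: str, records: Sequence[QCRecord]) -> None:
    """Write the whole table to a temp file, fsync, then rename into place."""
    directory = os.path.dirname(os.path.abspath(path)) or "."
    os.makedirs(directory, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".csv.tmp")
    try:
        with os.fdopen(fd, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for rec in records:
                writer.writerow(rec.row())
            fh.flush()
            os.fsync(fh.fileno())
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def load_table(path: str) -> QCTable:
    """Read an audit CSV back into a :class:`QCTable`."""
    records: list[QCRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != CSV_COLUMNS:
            raise ValueError(f"unexpected header in {path}: {header}")
        for row in reader:
            vals = dict(zip(CSV_COLUMNS, row))
            ident = ScanIdentifier(
                dataset=vals["dataset"], subject=vals["subject"],
                session=vals["session"], acquisition=vals["acquisition"],
                run=vals["run"], pipeline=vals["pipeline"], item=vals["item"])
            records.append(QCRecord(
                identifier=ident, status=vals["qc_status"], user=vals["user"],
                timestamp=vals["timestamp"], note=vals["reason"]))
    return QCTable(path, records)


def init_table(outputs: Sequence[ScanIdentifier], user: str,
               path: Optional[str] = None,
               timestamp: Optional[str] = None) -> QCTable:
    """Create an audit table with every output initialized to ``yes``.

    Reviewing then only records deviations.  Duplicate identifiers raise
    before anything is written.
    """
    keys = [i.key for i in outputs]
    if len(set(keys)) != len(keys):
        seen: set[tuple[str, ...]] = set()
        dups = [k for k in keys if k in seen or seen.add(k)]
        raise ValueError(f"duplicate identifiers: {dups}")
    ts = timestamp or utc_now()
    table = QCTable(path, (
        QCRecord(identifier=i, status="yes", user=user, timestamp=ts, note="")
        for i in outputs))
    table.save()
    return table


def upsert(table: QCTable, record: QCRecord) -> QCTable:
    """Replace one existing row and persist immediately (last write wins).

    QC never invents outputs: the record's identifier must already be in the
    table.
    """
    key = record.identifier.key
    if key not in table._rows:
        raise KeyError(f"identifier not in table: {key}")
    table._rows[key] = record
    table.save()
    return table


def ingest_failures(table: QCTable, reports: Sequence[FailureReport],
                    timestamp: Optional[str] = None) -> QCTable:
    """Record automatic failures: status ``no``, user ``auto``, note = reason.

    Reports for identifiers absent from the table are added as new rows.
    """
    ts = timestamp or utc_now()
    for rep in reports:
        table._rows[rep.identifier.key] = QCRecord(
            identifier=rep.identifier, status="no", user="auto",
            timestamp=ts, note=rep.reason)
    table.save()
    return table


def merge_tables(tables: Sequence[QCTable],
                 path: Optional[str] = None) -> QCTable:
    """Aggregate audit tables across datasets and pipelines into one table.

    Rows are the union; full-key collisions resolve to the latest timestamp
    (ties to the later table in the argument order); output order is the
    deterministic full-key sort.
    """
    merged: dict[tuple[str, ...], QCRecord] = {}
    for t in tables:
        for rec in t.records():
            key = rec.identifier.key
            if key in merged:
                if datetime.fromisoformat(rec.timestamp) >= datetime.fromisoformat(merged[key].timestamp):
                    merged[key] = rec
            else:
                merged[key] = rec
    out = QCTable(path, merged.values())
    out.save()
    return out
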