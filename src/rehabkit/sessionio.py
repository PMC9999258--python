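"""Session records, archives and summary reports.

A :class:`SessionRecord` is the durable unit the training client would upload
after each bout: a pseudonymous patient id, timestamp, the prescription item
trained, and the scored :class:`~rehabkit.scorer.SessionResult`, tagged with
software and schema versions.  Records round-trip through JSON; bouts
accumulate in a JSON-lines archive; :func:`report` aggregates an archive into
a per-day table (valid actions, mean session score, difficulty trajectory).
"""
from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field

import pandas as pd

from .prescribe import PrescriptionItem
from .scorer import SessionResult

SCHEMA_VERSION = "1.0"
SOFTWARE_VERSION = "0.1.0"


class RecordValidationError(ValueError):
    """Raised with the list of offending fields when a record is invalid."""

    def __init__(self, fields: list[str]):
        self.fields = fields
        super().__init__(f"invalid session record; offending fields: {fields}")


@dataclass
class SessionRecord:
    """One persisted training bout."""

    patient_id: str
    timestamp: str  # ISO-8601
    prescription: PrescriptionItem
    result: SessionResult
    software_version: str = SOFTWARE_VERSION
    schema_version: str = SCHEMA_VERSION

    def validate(self) -> None:
        bad = []
        if not self.patient_id:
            bad.append("patient_id")
        try:
            _dt.datetime.fromisoformat(self.timestamp)
        except (TypeError, ValueError):
            bad.append("timestamp")
        if not self.schema_version:
            bad.append("schema_version")
        if not self.software_version:
            bad.append("software_version")
        if not isinstance(self.prescription, PrescriptionItem):
            bad.append("prescription")
        if not isinstance(self.result, SessionResult):
            bad.append("result")
        if bad:
            raise RecordValidationError(bad)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "timestamp": self.timestamp,
            "prescription": self.prescription.to_dict(),
            "result": self.result.to_dict(),
            "software_version": self.software_version,
            "schema_version": self.schema_version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionRecord":
        missing = [
            k
            for k in ("patient_id", "timestamp", "prescription", "result", "schema_version")
            if k not in d
        ]
        if missing:
            raise RecordValidationError(missing)
        rec = cls(
            patient_id=d["patient_id"],
            timestamp=d["timestamp"],
            prescription=PrescriptionItem.from_dict(d["prescription"]),
            result=SessionResult.from_dict(d["result"]),
            software_version=d.get("software_version", SOFTWARE_VERSION),
            schema_version=d["schema_version"],
        )
        rec.validate()
        return rec


def write_session(record: SessionRecord, path) -> None:
    """Write one record as a JSON document."""
    record.validate()
    with open(path, "w") as fh:
        json.dump(record.to_dict(), fh, indent=2)


def read_session(path) -> SessionRecord:
    with open(path) as fh:
        return SessionRecord.from_dict(json.load(fh))


def append_session(record: SessionRecord, path) -> None:
    """Append one record to a JSON-lines archive."""
    record.validate()
    with open(path, "a") as fh:
        fh.write(json.dumps(record.to_dict()) + "\n")


def read_archive(path) -> list[SessionRecord]:
    """Read all records of a JSON-lines archive, in file order."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(SessionRecord.from_dict(json.loads(line)))
    return records


REPORT_COLUMNS = ["date", "sessions", "valid_count", "mean_session_score", "difficulty"]


def report(records: list[SessionRecord]) -> pd.DataFrame:
    """Per-day summary: bout count, total valid actions, mean session score,
    and the difficulty trajectory (difficulty of the day's last bout)."""
    if not records:
        return pd.DataFrame(columns=REPORT_COLUMNS)
    rows = [
        {
            "date": _dt.datetime.fromisoformat(r.timestamp).date().isoformat(),
            "timestamp": r.timestamp,
            "valid_count": r.result.valid_count,
            "session_score": r.result.session_score,
            "difficulty": r.result.difficulty,
        }
        for r in records
    ]
    df = pd.DataFrame(rows).sort_values("timestamp")
    out = (
        df.groupby("date")
        .agg(
            sessions=("session_score", "size"),
            valid_count=("valid_count", "sum"),
            mean_session_score=("session_score", "mean"),
            difficulty=("difficulty", "last"),
        )
        .reset_index()
    )
    return out[REPORT_COLUMNS]


def report_to_csv(records: list[SessionRecord], path) -> None:
    report(records).to_csv(path, index=False)
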