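"""Usage-log data model, TSV serialization, and sessionization.

A usage log is one row per user event: the session it belongs to, the
institution it came from, a seconds-resolution timestamp, the action type
(free-text search, topic view, or subtopic view), and a payload — the query
string for searches, a topic identifier otherwise.  Subtopic views carry the
parent topic identifier plus a ``/``-separated suffix (``lipitor/dosing``),
so a click within a topic page can be folded back onto its parent topic.

All timestamps in one file are interpreted in a single declared timezone;
they are stored as naive datetimes and downstream daily/monthly aggregation
uses that timezone's calendar dates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union


class Action(str, Enum):
    """The three event types a usage log records."""

    SEARCH = "search"
    TOPIC_VIEW = "topic_view"
    SUBTOPIC_VIEW = "subtopic_view"


#: separator between a parent topic id and a subtopic suffix in the payload
SUBTOPIC_SEP = "/"


class LogParseError(ValueError):
    """A malformed log row; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True, slots=True)
class LogEvent:
    """One timestamped user action within a session."""

    session_id: str
    institution_id: str
    timestamp: datetime
    action: Action
    payload: str

    def __post_init__(self):
        if not isinstance(self.action, Action):
            object.__setattr__(self, "action", Action(self.action))
        if not self.payload:
            raise ValueError("LogEvent payload must be non-empty")

    @property
    def topic_id(self) -> str | None:
        """Topic identifier of a view event (parent topic for subtopic views)."""
        if self.action is Action.TOPIC_VIEW:
            return self.payload
        if self.action is Action.SUBTOPIC_VIEW:
            return self.payload.split(SUBTOPIC_SEP, 1)[0]
        return None

    @property
    def is_view(self) -> bool:
        return self.action is not Action.SEARCH


@dataclass(frozen=True)
class LogDialect:
    """Physical format of a log file.

    ``timestamp_format`` is a ``strptime`` pattern, or ``"iso"`` for ISO-8601.
    ``timezone`` is declarative: all timestamps in the file are calendar
    times in that zone and are kept naive.
    """

    delimiter: str = "\t"
    timestamp_format: str = "iso"
    timezone: str = "UTC"
    columns: tuple[str, ...] = (
        "session_id",
        "institution_id",
        "timestamp",
        "action",
        "payload",
    )
    has_header: bool = True
    comment_char: str = "#"

    def parse_timestamp(self, text: str) -> datetime:
        if self.timestamp_format == "iso":
            return datetime.fromisoformat(text)
        return datetime.strptime(text, self.timestamp_format)

    def format_timestamp(self, ts: datetime) -> str:
        if self.timestamp_format == "iso":
            return ts.isoformat(sep="T")
        return ts.strftime(self.timestamp_format)


DEFAULT_DIALECT = LogDialect()

_VALID_ACTIONS = {a.value for a in Action}


@dataclass
class Session:
    """All events sharing one session id, ordered by timestamp.

    Ties at equal timestamps preserve input-file order, so downstream dwell
    computation is deterministic.
    """

    session_id: str
    events: list[LogEvent]

    def __post_init__(self):
        for e in self.events:
            if e.session_id != self.session_id:
                raise ValueError(
                    f"event session_id {e.session_id!r} != {self.session_id!r}"
                )
        for a, b in zip(self.events, self.events[1:]):
            if b.timestamp < a.timestamp:
                raise ValueError("session events must be time-ordered")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def _parse_row(
    row: Sequence[str], line_number: int, dialect: LogDialect
) -> LogEvent:
    if len(row) != len(dialect.columns):
        raise LogParseError(
            line_number,
            f"expected {len(dialect.columns)} columns, got {len(row)}",
        )
    fields = dict(zip(dialect.columns, row))
    if fields["action"] not in _VALID_ACTIONS:
        raise LogParseError(line_number, f"unknown action {fields['action']!r}")
    if not fields["payload"]:
        raise LogParseError(line_number, "empty payload")
    try:
        ts = dialect.parse_timestamp(fields["timestamp"])
    except ValueError as exc:
        raise LogParseError(
            line_number, f"unparseable timestamp {fields['timestamp']!r}: {exc}"
        ) from None
    return LogEvent(
        session_id=fields["session_id"],
        institution_id=fields["institution_id"],
        timestamp=ts,
        action=Action(fields["action"]),
        payload=fields["payload"],
    )


def read_log(
    path: Union[str, Path], dialect: LogDialect = DEFAULT_DIALECT
) -> list[LogEvent]:
    """Read a usage log, one :class:`LogEvent` per well-formed row.

    Raises :class:`LogParseError` (naming the line) on the first malformed
    row.  ``#``-prefixed lines are comments/headers and are skipped.
    """
    events: list[LogEvent] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter, quotechar='"')
        for line_number, row in enumerate(reader, start=1):
            if not row:
                continue
            if row[0].startswith(dialect.comment_char):
                continue
            events.append(_parse_row(row, line_number, dialect))
    return events


def write_log(
    events: Iterable[LogEvent],
    path: Union[str, Path],
    dialect: LogDialect = DEFAULT_DIALECT,
    header_comment: str | None = None,
) -> None:
    """Write events so that :func:`read_log` round-trips them exactly.

    Payloads containing the delimiter are quoted by the csv layer.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if dialect.has_header:
            fh.write(dialect.comment_char + dialect.delimiter.join(dialect.columns) + "\n")
        if header_comment:
            fh.write(f"{dialect.comment_char} {header_comment}\n")
        writer = csv.writer(fh, delimiter=dialect.delimiter, quotechar='"')
        for e in events:
            writer.writerow(
                [
                    e.session_id,
                    e.institution_id,
                    dialect.format_timestamp(e.timestamp),
                    e.action.value,
                    e.payload,
                ]
            )


def group_sessions(events: Sequence[LogEvent]) -> list[Session]:
    """Partition events into sessions and time-order each session.

    Sessions are emitted in order of first appearance in the input; within a
    session the sort on timestamp is stable, so equal-timestamp events keep
    input order.
    """
    by_id: dict[str, list[LogEvent]] = {}
    for e in events:
        by_id.setdefault(e.session_id, []).append(e)
    return [
        Session(sid, sorted(evs, key=lambda e: e.timestamp))
        for sid, evs in by_id.items()
    ]


def validate_log(
    path: Union[str, Path], dialect: LogDialect = DEFAULT_DIALECT
) -> dict:
    """Row-count and malformed-row diagnostics for a log file.

    Unlike :func:`read_log` this does not stop at the first bad row; it
    returns ``{"counts": {action: n}, "errors": [(line, message), ...],
    "n_rows": total}`` for the CLI ``validate`` command.
    """
    counts = {a.value: 0 for a in Action}
    errors: list[tuple[int, str]] = []
    n_rows = 0
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter, quotechar='"')
        for line_number, row in enumerate(reader, start=1):
            if not row or row[0].startswith(dialect.comment_char):
                continue
            n_rows += 1
            try:
                ev = _parse_row(row, line_number, dialect)
            except LogParseError as exc:
                errors.append((exc.line_number, str(exc)))
            else:
                counts[ev.action.value] += 1
    return {"counts": counts, "errors": errors, "n_rows": n_rows}
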