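"""Data model and I/O for pathologists' viewport-tracking logs.

A *viewport* is the rectangular slide region visible on the pathologist's
screen at one moment, logged together with the magnification and a timestamp.
All coordinates live in pixels of the 10x reference frame, 0-based, with
half-open rectangles ``[x, x+w) x [y, y+h)``.  An *interpretation* is one
pathologist's complete viewing session for one case.

Two on-disk dialects are supported: CSV with the fixed header
``case_id,pathologist_id,timestamp_s,x,y,width,height,zoom`` and JSONL with
one object per record using the same keys.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "ViewportRecord",
    "Interpretation",
    "CaseMeta",
    "PathologistGroup",
    "LogParseError",
    "RecordValidationError",
    "assign_durations",
    "parse_viewport_log",
    "serialize_viewport_log",
    "read_case_table",
    "write_case_table",
    "read_interpretation_table",
    "write_interpretation_table",
    "attach_metadata",
]

CSV_HEADER = ["case_id", "pathologist_id", "timestamp_s", "x", "y", "width", "height", "zoom"]
CASE_TABLE_HEADER = ["case_id", "consensus_class", "slide_path"]
INTERP_TABLE_HEADER = ["case_id", "pathologist_id", "diagnosis_class", "group"]

VALID_CLASSES = (1, 2, 3, 4)


class LogParseError(ValueError):
    """Structural problem with a log stream (e.g. missing column)."""


class RecordValidationError(ValueError):
    """A single log row violates a record invariant; carries the row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(f"row {row}: {message}" if row is not None else message)
        self.row = row


class PathologistGroup(str, Enum):
    community = "community"
    consensus_panel = "consensus_panel"


@dataclass(frozen=True)
class ViewportRecord:
    """One log entry: a viewport rectangle, its magnification and timestamp.

    ``duration`` is derived (time until the next entry); the final entry of a
    session has duration 0 because the logs carry no end-of-session marker.
    """

    x: int
    y: int
    width: int
    height: int
    zoom: float
    timestamp: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise RecordValidationError(
                f"viewport width/height must be positive, got {self.width}x{self.height}"
            )
        if self.zoom <= 0:
            raise RecordValidationError(f"zoom must be positive, got {self.zoom}")
        if self.duration < 0:
            raise RecordValidationError(f"duration must be >= 0, got {self.duration}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)

    @property
    def rect(self) -> tuple[int, int, int, int]:
        """(x, y, width, height) in reference-frame pixels, half-open."""
        return (self.x, self.y, self.width, self.height)


@dataclass
class Interpretation:
    """One (case, pathologist) viewing session plus its diagnosis."""

    case_id: str
    pathologist_id: str
    records: list[ViewportRecord] = field(default_factory=list)
    diagnosis_class: int | None = None
    pathologist_group: PathologistGroup = PathologistGroup.community

    def __post_init__(self) -> None:
        if self.diagnosis_class is not None and self.diagnosis_class not in VALID_CLASSES:
            raise ValueError(f"diagnosis_class must be in 1..4, got {self.diagnosis_class}")
        ts = [r.timestamp for r in self.records]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("records must be sorted by timestamp")


@dataclass(frozen=True)
class CaseMeta:
    """Per-case metadata: consensus diagnosis, slide location, frame size."""

    case_id: str
    consensus_class: int
    slide_path: str
    frame_width: int = 0
    frame_height: int = 0

    def __post_init__(self) -> None:
        if self.consensus_class not in VALID_CLASSES:
            raise ValueError(f"consensus_class must be in 1..4, got {self.consensus_class}")
        if self.frame_width < 0 or self.frame_height < 0:
            raise ValueError("frame dimensions must be nonnegative")


def assign_durations(records: Sequence[ViewportRecord]) -> list[ViewportRecord]:
    """Derive per-entry dwell durations from consecutive timestamps.

    ``duration_i = timestamp_{i+1} - timestamp_i``; the last record gets 0.
    The sum of durations therefore equals the session span.
    """
    ts = [r.timestamp for r in records]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError("records must be sorted by timestamp before assigning durations")
    out = []
    for i, rec in enumerate(records):
        dur = ts[i + 1] - ts[i] if i + 1 < len(ts) else 0.0
        out.append(replace(rec, duration=dur))
    return out


def _record_from_mapping(row: dict, rownum: int) -> tuple[str, str, ViewportRecord]:
    for col in CSV_HEADER:
        if col not in row or row[col] in (None, ""):
            raise LogParseError(f"missing required column '{col}' (row {rownum})")
    try:
        rec = ViewportRecord(
            x=int(row["x"]),
            y=int(row["y"]),
            width=int(row["width"]),
            height=int(row["height"]),
            zoom=float(row["zoom"]),
            timestamp=float(row["timestamp_s"]),
        )
    except RecordValidationError as err:
        raise RecordValidationError(str(err), row=rownum) from None
    except (TypeError, ValueError) as err:
        raise RecordValidationError(f"malformed value: {err}", row=rownum) from None
    return str(row["case_id"]), str(row["pathologist_id"]), rec


def parse_viewport_log(stream: io.TextIOBase | str, dialect: str = "csv") -> list[Interpretation]:
    """Parse a viewport log into interpretations.

    Rows are grouped by ``(case_id, pathologist_id)`` and sorted by timestamp
    within each group; the grouping is canonical (sorted by key), so the
    result is invariant to input row order.  Durations are derived.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    grouped: dict[tuple[str, str], list[ViewportRecord]] = {}
    if dialect == "csv":
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            return []
        missing = [c for c in CSV_HEADER if c not in reader.fieldnames]
        if missing:
            raise LogParseError(f"missing required column '{missing[0]}' in header")
        rows: Iterable[tuple[dict, int]] = ((row, i) for i, row in enumerate(reader, start=2))
    elif dialect == "jsonl":
        def _jsonl_rows():
            for i, line in enumerate(stream, start=1):
                line = line.strip()
                if line:
                    yield json.loads(line), i
        rows = _jsonl_rows()
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'csv' or 'jsonl')")

    for row, rownum in rows:
        case_id, path_id, rec = _record_from_mapping(row, rownum)
        grouped.setdefault((case_id, path_id), []).append(rec)

    interps = []
    for (case_id, path_id) in sorted(grouped):
        recs = sorted(grouped[(case_id, path_id)], key=lambda r: r.timestamp)
        interps.append(
            Interpretation(case_id=case_id, pathologist_id=path_id, records=assign_durations(recs))
        )
    return interps


def serialize_viewport_log(interps: Iterable[Interpretation], dialect: str = "csv") -> str:
    """Serialize interpretations so that ``parse_viewport_log`` round-trips them."""
    rows = []
    for interp in interps:
        for rec in interp.records:
            rows.append(
                {
                    "case_id": interp.case_id,
                    "pathologist_id": interp.pathologist_id,
                    "timestamp_s": repr(rec.timestamp),
                    "x": rec.x,
                    "y": rec.y,
                    "width": rec.width,
                    "height": rec.height,
                    "zoom": repr(rec.zoom),
                }
            )
    if dialect == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=CSV_HEADER, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
        return buf.getvalue()
    if dialect == "jsonl":
        out = []
        for row in rows:
            row = dict(row, timestamp_s=float(row["timestamp_s"]), zoom=float(row["zoom"]))
            out.append(json.dumps(row))
        return "\n".join(out) + ("\n" if out else "")
    raise ValueError(f"unknown dialect {dialect!r}")


def read_case_table(stream: io.TextIOBase | str) -> list[CaseMeta]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream)
    out = []
    for row in reader:
        out.append(
            CaseMeta(
                case_id=str(row["case_id"]),
                consensus_class=int(row["consensus_class"]),
                slide_path=str(row["slide_path"]),
            )
        )
    return out


def write_case_table(cases: Iterable[CaseMeta]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CASE_TABLE_HEADER)
    for c in cases:
        writer.writerow([c.case_id, c.consensus_class, c.slide_path])
    return buf.getvalue()


def read_interpretation_table(stream: io.TextIOBase | str) -> dict[tuple[str, str], tuple[int, PathologistGroup]]:
    """Read (case, pathologist) -> (diagnosis_class, group) assignments."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream)
    out = {}
    for row in reader:
        key = (str(row["case_id"]), str(row["pathologist_id"]))
        out[key] = (int(row["diagnosis_class"]), PathologistGroup(row["group"]))
    return out


def write_interpretation_table(interps: Iterable[Interpretation]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(INTERP_TABLE_HEADER)
    for it in interps:
        writer.writerow(
            [it.case_id, it.pathologist_id, it.diagnosis_class, it.pathologist_group.value]
        )
    return buf.getvalue()


def attach_metadata(
    interps: Iterable[Interpretation],
    table: dict[tuple[str, str], tuple[int, PathologistGroup]],
) -> list[Interpretation]:
    """Attach diagnosis class and pathologist group from the interpretation table."""
    out = []
    for it in interps:
        key = (it.case_id, it.pathologist_id)
        if key in table:
            diag, group = table[key]
            it = Interpretation(
                case_id=it.case_id,
                pathologist_id=it.pathologist_id,
                records=it.records,
                diagnosis_class=diag,
                pathologist_group=group,
            )
        out.append(it)
    return out
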