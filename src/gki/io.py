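"""CSV reading and writing for measurement logs.

Two layouts are supported, both comma-separated UTF-8 with a mandatory
header row and ISO-8601 timestamps:

* **paired** — one row per measurement:
  ``timestamp,glucose,glucose_unit,ketone,ketone_unit,ketone_source,postprandial_hours,note``
* **interleaved** — one row per single-analyte reading (the layout many
  meters export): ``timestamp,analyte,value,unit,ketone_source,note``;
  glucose and ketone rows are paired when their timestamps fall within a
  pairing window (default 10 minutes), and unpaired rows are dropped with a
  row-numbered diagnostic.

Unit columns are mandatory for every value — a file that does not declare
units is rejected outright rather than guessed at.  Values are serialized
at full precision; rounding happens only at display time.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

from .tracking import Measurement, TrackingLog
from .units import Analyte, Concentration, Unit, ValidationError

__all__ = ["ParseReport", "read_log", "write_log", "PAIRED_COLUMNS"]

logger = logging.getLogger(__name__)

PAIRED_COLUMNS = (
    "timestamp",
    "glucose",
    "glucose_unit",
    "ketone",
    "ketone_unit",
    "ketone_source",
    "postprandial_hours",
    "note",
)
INTERLEAVED_COLUMNS = ("timestamp", "analyte", "value", "unit")

DEFAULT_PAIRING_WINDOW = dt.timedelta(minutes=10)


@dataclass
class ParseReport:
    """Row-level accounting for a log file parse."""

    rows_read: int = 0
    rows_used: int = 0
    rows_dropped: int = 0
    warnings: list[str] = field(default_factory=list)

    def warn(self, row: int, message: str) -> None:
        self.warnings.append(f"row {row}: {message}")
        logger.warning("row %d: %s", row, message)


def _parse_timestamp(text: str, row: int, report: ParseReport) -> Optional[dt.datetime]:
    try:
        return dt.datetime.fromisoformat(text.strip())
    except ValueError:
        report.warn(row, f"unparseable timestamp {text!r}")
        return None


def read_log(
    path: str | Path,
    format: Literal["paired", "interleaved"] = "paired",
    subject_id: str = "",
    pairing_window: dt.timedelta = DEFAULT_PAIRING_WINDOW,
) -> tuple[TrackingLog, ParseReport]:
    """Read a measurement CSV into a :class:`TrackingLog` plus parse report.

    Malformed rows are dropped with diagnostics rather than aborting the
    whole file; a missing unit column, however, is a hard error because the
    numbers are meaningless without it.  An empty file yields an empty log
    and a warning.
    """
    path = Path(path)
    if format not in ("paired", "interleaved"):
        raise ValidationError(f"unknown log format: {format!r}")
    subject = subject_id or path.stem
    report = ParseReport()

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames
        if header is None:
            report.warnings.append("empty file")
            logger.warning("%s: empty file", path)
            return TrackingLog(subject, []), report
        required = PAIRED_COLUMNS[:5] if format == "paired" else INTERLEAVED_COLUMNS
        missing = [c for c in required if c not in header]
        if missing:
            raise ValidationError(f"{path}: missing required column(s) {missing}")
        rows = list(reader)

    report.rows_read = len(rows)
    if format == "paired":
        measurements = _parse_paired(rows, report)
    else:
        measurements = _parse_interleaved(rows, report, pairing_window)
    report.rows_used = report.rows_read - report.rows_dropped
    return TrackingLog(subject, measurements), report


def _parse_paired(rows: list[dict], report: ParseReport) -> list[Measurement]:
    measurements = []
    for i, r in enumerate(rows, start=2):  # header is row 1
        ts = _parse_timestamp(r["timestamp"], i, report)
        if ts is None:
            report.rows_dropped += 1
            continue
        try:
            glucose = Concentration(
                Analyte.GLUCOSE, float(r["glucose"]), Unit.from_label(r["glucose_unit"])
            )
            ketone = Concentration(
                Analyte.BETA_HYDROXYBUTYRATE,
                float(r["ketone"]),
                Unit.from_label(r["ketone_unit"]),
            )
            pp_raw = (r.get("postprandial_hours") or "").strip()
            measurements.append(
                Measurement(
                    timestamp=ts,
                    glucose=glucose,
                    ketone=ketone,
                    ketone_source=(r.get("ketone_source") or "blood").strip() or "blood",
                    postprandial_hours=float(pp_raw) if pp_raw else None,
                    note=(r.get("note") or "").strip(),
                )
            )
        except (ValueError, ValidationError) as exc:
            report.warn(i, str(exc))
            report.rows_dropped += 1
    return measurements


def _parse_interleaved(
    rows: list[dict], report: ParseReport, window: dt.timedelta
) -> list[Measurement]:
    """Pair single-analyte rows by timestamp proximity.

    Greedy in time order: each glucose row is paired with the nearest
    still-unpaired ketone row within the window.  The measurement takes the
    glucose row's timestamp.
    """
    glucose_rows: list[tuple[int, dt.datetime, Concentration]] = []
    ketone_rows: list[tuple[int, dt.datetime, Concentration, str]] = []
    for i, r in enumerate(rows, start=2):
        ts = _parse_timestamp(r["timestamp"], i, report)
        if ts is None:
            report.rows_dropped += 1
            continue
        try:
            analyte = Analyte.from_label(r["analyte"])
            conc = Concentration(analyte, float(r["value"]), Unit.from_label(r["unit"]))
        except (ValueError, ValidationError) as exc:
            report.warn(i, str(exc))
            report.rows_dropped += 1
            continue
        if analyte is Analyte.GLUCOSE:
            glucose_rows.append((i, ts, conc))
        else:
            source = (r.get("ketone_source") or "blood").strip() or "blood"
            ketone_rows.append((i, ts, conc, source))

    glucose_rows.sort(key=lambda t: t[1])
    ketone_rows.sort(key=lambda t: t[1])
    used_ketone = [False] * len(ketone_rows)
    measurements = []
    for g_row, g_ts, g_conc in glucose_rows:
        best_j, best_gap = None, window
        for j, (_, k_ts, _, _) in enumerate(ketone_rows):
            if used_ketone[j]:
                continue
            gap = abs(k_ts - g_ts)
            if gap <= best_gap:
                best_j, best_gap = j, gap
        if best_j is None:
            report.warn(g_row, "glucose reading has no ketone partner within pairing window")
            report.rows_dropped += 1
            continue
        used_ketone[best_j] = True
        _, _, k_conc, k_source = ketone_rows[best_j]
        try:
            measurements.append(
                Measurement(
                    timestamp=g_ts,
                    glucose=g_conc,
                    ketone=k_conc,
                    ketone_source=k_source,  # type: ignore[arg-type]
                )
            )
        except ValidationError as exc:
            report.warn(g_row, str(exc))
            report.rows_dropped += 1
    for j, used in enumerate(used_ketone):
        if not used:
            report.warn(ketone_rows[j][0], "ketone reading has no glucose partner within pairing window")
            report.rows_dropped += 1
    return measurements


def write_log(log: TrackingLog, path: str | Path) -> None:
    """Write a log in the paired CSV layout, full precision, ISO timestamps."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PAIRED_COLUMNS)
        for m in log:
            writer.writerow(
                [
                    m.timestamp.isoformat(),
                    repr(m.glucose.value),
                    m.glucose.unit.value,
                    repr(m.ketone.value),
                    m.ketone.unit.value,
                    m.ketone_source,
                    "" if m.postprandial_hours is None else repr(m.postprandial_hours),
                    m.note,
                ]
            )
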