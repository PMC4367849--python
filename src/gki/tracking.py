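"""Time-ordered measurement logs and therapeutic target-zone accounting.

A subject on a ketogenic or calorie-restricted diet records paired glucose
and β-OHB readings, ideally 2–3 hours postprandial and twice daily.  This
module turns such a log into a per-reading GKI series, aggregates it to one
value per calendar day, classifies each day against a target GKI (default
1.0, the value considered potentially most therapeutic; the zone of
metabolic management is likely entered between 1 and 2), and counts the
days spent in the zone.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Literal, Optional, Sequence

from .units import (
    Analyte,
    Concentration,
    GkiValue,
    ValidationError,
    compute_gki,
)

__all__ = [
    "Measurement",
    "TrackingLog",
    "ZoneConfig",
    "DayRecord",
    "ZoneReport",
    "SeriesPoint",
    "gki_series",
    "daily_aggregate",
    "evaluate_zone",
    "monthly_view",
]

DailyRule = Literal["mean", "all_readings"]


@dataclass(frozen=True)
class Measurement:
    """One timestamped paired glucose + ketone reading.

    ``ketone_source`` records whether the ketone value came from a blood
    meter (the β-OHB measurement the GKI is defined on) or from a urine
    strip; urinary values yield a GKI arithmetically but are flagged
    non-comparable downstream because urinary acetoacetate is not blood
    β-OHB.
    """

    timestamp: dt.datetime
    glucose: Concentration
    ketone: Concentration
    ketone_source: Literal["blood", "urine"] = "blood"
    postprandial_hours: Optional[float] = None
    note: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.timestamp, dt.datetime):
            raise ValidationError(f"timestamp must be a datetime, got {self.timestamp!r}")
        if self.glucose.analyte is not Analyte.GLUCOSE:
            raise ValidationError("glucose concentration must carry the glucose analyte")
        if self.ketone.analyte is not Analyte.BETA_HYDROXYBUTYRATE:
            raise ValidationError("ketone concentration must carry the β-OHB analyte")
        if self.ketone.value <= 0:
            raise ValidationError("ketone reading must be strictly positive (GKI undefined at zero)")
        if self.ketone_source not in ("blood", "urine"):
            raise ValidationError(f"ketone_source must be 'blood' or 'urine', got {self.ketone_source!r}")
        if self.postprandial_hours is not None and self.postprandial_hours < 0:
            raise ValidationError("postprandial_hours must be non-negative")

    @property
    def gki(self) -> GkiValue:
        return compute_gki(self.glucose, self.ketone)

    @property
    def date(self) -> dt.date:
        """Calendar date of the reading; no timezone conversion is applied."""
        return self.timestamp.date()


@dataclass(frozen=True)
class TrackingLog:
    """Time-ordered sequence of measurements for one subject.

    Construction sorts by timestamp and rejects exact duplicate timestamps:
    two readings cannot share an instant, and silent overwriting would hide
    meter-export glitches.
    """

    subject_id: str
    measurements: tuple[Measurement, ...]

    def __init__(self, subject_id: str, measurements: Iterable[Measurement]):
        ms = sorted(measurements, key=lambda m: m.timestamp)
        for a, b in zip(ms, ms[1:]):
            if a.timestamp == b.timestamp:
                raise ValidationError(f"duplicate timestamp in log: {a.timestamp.isoformat()}")
        object.__setattr__(self, "subject_id", subject_id)
        object.__setattr__(self, "measurements", tuple(ms))

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    @property
    def dates(self) -> list[dt.date]:
        """Distinct calendar dates with at least one measurement, ascending."""
        return sorted({m.date for m in self.measurements})


@dataclass(frozen=True)
class ZoneConfig:
    """Target-zone definition for days-in-zone accounting.

    ``target`` is the GKI at or below which a day counts as in the zone
    (default 1.0).  ``upper_band`` is the upper edge of the broader 1–2
    management band, kept for reporting; it does not affect the in-zone
    test.  Leaving it ``None`` resolves to the conventional 2.0, or to the
    target itself when the target is set above 2 (the band edge never sits
    below the target).  ``daily_rule`` selects how multiple same-day
    readings collapse to one daily value: ``mean`` (default) or
    ``all_readings``, which takes the day's maximum so the day is in zone
    only if every reading is.
    """

    target: float = 1.0
    upper_band: Optional[float] = None
    daily_rule: DailyRule = "mean"

    def __post_init__(self) -> None:
        if self.target <= 0:
            raise ValidationError("target must be positive")
        if self.upper_band is None:
            object.__setattr__(self, "upper_band", max(2.0, self.target))
        else:
            if self.upper_band <= 0:
                raise ValidationError("upper_band must be positive")
            if self.target > self.upper_band:
                raise ValidationError("target must not exceed upper_band")
        if self.daily_rule not in ("mean", "all_readings"):
            raise ValidationError(f"unknown daily_rule: {self.daily_rule!r}")


@dataclass(frozen=True)
class SeriesPoint:
    timestamp: dt.datetime
    gki: GkiValue
    urine_ketone: bool = False


@dataclass(frozen=True)
class DayRecord:
    date: dt.date
    gki: float
    in_zone: bool
    n_readings: int = 1
    urine_ketone: bool = False


@dataclass(frozen=True)
class ZoneReport:
    """Per-day zone classification plus aggregate counts.

    ``entry_dates`` lists the dates on which the subject transitioned from
    out-of-zone to in-zone (the first in-zone day counts as an entry).
    """

    per_day: tuple[DayRecord, ...]
    days_in_zone: int
    total_days: int
    entry_dates: tuple[dt.date, ...]
    target: float
    daily_rule: DailyRule = "mean"
    non_comparable_days: tuple[dt.date, ...] = field(default_factory=tuple)


def gki_series(log: TrackingLog) -> list[SeriesPoint]:
    """One GKI per measurement, in timestamp order.

    Urine-sourced readings are included (the ratio is still computable) but
    flagged so reports can mark them non-comparable with blood β-OHB values.
    An empty log yields an empty series.
    """
    return [
        SeriesPoint(m.timestamp, m.gki, urine_ketone=(m.ketone_source == "urine"))
        for m in log
    ]


def _daily_groups(log: TrackingLog) -> dict[dt.date, list[Measurement]]:
    groups: dict[dt.date, list[Measurement]] = {}
    for m in log:
        groups.setdefault(m.date, []).append(m)
    return dict(sorted(groups.items()))


def daily_aggregate(log: TrackingLog, rule: DailyRule = "mean") -> list[tuple[dt.date, float]]:
    """Collapse each calendar day's readings to one GKI.

    ``mean`` takes the arithmetic mean of that day's per-reading GKIs;
    ``all_readings`` takes the maximum, so a day is later judged in-zone only
    if all of its readings were at or below the target.
    """
    if rule not in ("mean", "all_readings"):
        raise ValidationError(f"unknown daily rule: {rule!r}")
    out: list[tuple[dt.date, float]] = []
    for date, ms in _daily_groups(log).items():
        gkis = [m.gki.value for m in ms]
        out.append((date, fmean(gkis) if rule == "mean" else max(gkis)))
    return out


def evaluate_zone(log: TrackingLog, cfg: ZoneConfig = ZoneConfig()) -> ZoneReport:
    """Classify each day against the target and count days in zone.

    A day is in the zone iff its daily GKI is ≤ ``cfg.target`` (the boundary
    is inclusive: a day sitting exactly on the target line counts).
    """
    groups = _daily_groups(log)
    per_day: list[DayRecord] = []
    entry_dates: list[dt.date] = []
    non_comparable: list[dt.date] = []
    prev_in = False
    for date, ms in groups.items():
        gkis = [m.gki.value for m in ms]
        daily = fmean(gkis) if cfg.daily_rule == "mean" else max(gkis)
        in_zone = daily <= cfg.target
        urine = any(m.ketone_source == "urine" for m in ms)
        per_day.append(DayRecord(date, daily, in_zone, n_readings=len(ms), urine_ketone=urine))
        if urine:
            non_comparable.append(date)
        if in_zone and not prev_in:
            entry_dates.append(date)
        prev_in = in_zone
    return ZoneReport(
        per_day=tuple(per_day),
        days_in_zone=sum(d.in_zone for d in per_day),
        total_days=len(per_day),
        entry_dates=tuple(entry_dates),
        target=cfg.target,
        daily_rule=cfg.daily_rule,
        non_comparable_days=tuple(non_comparable),
    )


def monthly_view(log: TrackingLog, cfg: ZoneConfig, month: str | tuple[int, int]):
    """Plot-ready table of one month's daily GKI against the target line.

    ``month`` is "YYYY-MM" or a (year, month) pair.  Returns a pandas
    DataFrame with columns ``day`` (day of month), ``date``, ``gki`` and the
    constant ``target`` — the table behind the monthly tracking chart, where
    daily GKI is drawn as a line and the target as a horizontal line.
    A month with no data yields an empty table (and a logged warning).
    """
    import logging

    import pandas as pd

    if isinstance(month, str):
        year_s, month_s = month.split("-")
        year, mon = int(year_s), int(month_s)
    else:
        year, mon = month
    if not 1 <= mon <= 12:
        raise ValidationError(f"month out of range: {mon}")

    rows = [
        {"day": date.day, "date": date, "gki": daily, "target": cfg.target}
        for date, daily in daily_aggregate(log, cfg.daily_rule)
        if date.year == year and date.month == mon
    ]
    if not rows:
        logging.getLogger(__name__).warning("no measurements in %04d-%02d", year, mon)
        return pd.DataFrame(columns=["day", "date", "gki", "target"])
    return pd.DataFrame(rows)
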