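import datetime as dt
from statistics import fmean

import pytest

from gki import Analyte, Concentration, Measurement, TrackingLog, Unit


def make_measurement(
    ts: dt.datetime,
    glucose_mm: float,
    ketone_mm: float,
    ketone_source: str = "blood",
) -> Measurement:
    return Measurement(
        timestamp=ts,
        glucose=Concentration(Analyte.GLUCOSE, glucose_mm, Unit.MM),
        ketone=Concentration(Analyte.BETA_HYDROXYBUTYRATE, ketone_mm, Unit.MM),
        ketone_source=ketone_source,
    )


def make_log(pairs, start=dt.datetime(2015, 3, 1, 8)) -> TrackingLog:
    """Log with one (glucose mM, ketone mM) measurement per day."""
    return TrackingLog(
        "test",
        [
            make_measurement(start + dt.timedelta(days=i), g, k)
            for i, (g, k) in enumerate(pairs)
        ],
    )


def brute_force_zone(log: TrackingLog, target: float, rule: str = "mean"):
    """Independent per-day re-scan of a log: (per-day dict, days_in_zone,
    total_days, entry_dates).  Deliberately naive; used as the oracle for
    ZoneReport."""
    days = sorted({m.timestamp.date() for m in log})
    per_day = {}
    for day in days:
        gkis = [
            m.glucose.mM / m.ketone.mM
            for m in log
            if m.timestamp.date() == day
        ]
        daily = fmean(gkis) if rule == "mean" else max(gkis)
        per_day[day] = (daily, daily <= target)
    entries = []
    prev = False
    for day in days:
        in_zone = per_day[day][1]
        if in_zone and not prev:
            entries.append(day)
        prev = in_zone
    return per_day, sum(v[1] for v in per_day.values()), len(days), entries


@pytest.fixture(scope="session")
def table1_records():
    from gki import load_table1_fixtures

    return load_table1_fixtures()
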