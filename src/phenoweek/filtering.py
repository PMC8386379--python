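"""Daily and weekly data-sufficiency rules and weekly aggregation.

A participant-day is *sufficient* when (1) at least one of the seven
minutely-sampled sensors recorded at least 720 distinct minutes (half a
day) and (2) the app was active (>= 1 ping) in at least 18 distinct hours
of the day.  A participant-week is retained when at least 3 of its 7 days
are sufficient; daily feature values on sufficient days are then averaged
into the weekly value.  A specific feature may still end up missing in a
retained week if no sufficient day carries a value for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MINUTELY_SENSORS

__all__ = [
    "MIN_MINUTES",
    "MIN_ACTIVE_HOURS",
    "MIN_SUFFICIENT_DAYS",
    "DaySufficiency",
    "assess_day",
    "assess_week",
    "aggregate_week",
    "daily_sufficiency",
]

MIN_MINUTES = 720
MIN_ACTIVE_HOURS = 18
MIN_SUFFICIENT_DAYS = 3


@dataclass
class DaySufficiency:
    """Sufficiency assessment for one participant-day."""

    participant_id: str
    date: object
    minutes_available: dict[str, int] = field(default_factory=dict)
    active_hours: int = 0
    sufficient: bool = False


def _distinct_minutes(timestamps: Sequence) -> np.ndarray:
    ts = pd.DatetimeIndex(pd.to_datetime(list(timestamps)))
    return np.unique(ts.floor("min").asi8)


def assess_day(samples: Mapping[str, Sequence], participant_id: str = "", date=None) -> DaySufficiency:
    """Assess one participant-day from per-sensor sample timestamps.

    ``samples`` maps sensor name to the timestamps observed that day; only
    the seven minutely sensors count toward the 720-minute rule, and the
    ``ping`` stream defines app-active hours.  All timestamps must share a
    single calendar date.
    """
    dates = set()
    minutes: dict[str, int] = {}
    active_hours = 0
    for sensor, ts in samples.items():
        if len(ts) == 0:
            continue
        idx = pd.DatetimeIndex(pd.to_datetime(list(ts)))
        dates.update(idx.normalize().unique())
        if sensor in MINUTELY_SENSORS:
            minutes[sensor] = int(len(np.unique(idx.floor("min").asi8)))
        if sensor == "ping":
            active_hours = int(idx.hour.nunique())
    if len(dates) > 1:
        raise ValueError("assess_day received samples spanning multiple dates")
    if date is None and dates:
        date = next(iter(dates)).date()
    best = max(minutes.values(), default=0)
    sufficient = best >= MIN_MINUTES and active_hours >= MIN_ACTIVE_HOURS
    return DaySufficiency(
        participant_id=participant_id,
        date=date,
        minutes_available=minutes,
        active_hours=active_hours,
        sufficient=sufficient,
    )


def assess_week(day_records: Sequence[DaySufficiency] | Sequence[bool]) -> bool:
    """True iff a 7-day block holds 3 or more sufficient days."""
    if len(day_records) != 7:
        raise ValueError(f"a study week has 7 days, got {len(day_records)}")
    flags = [d.sufficient if isinstance(d, DaySufficiency) else bool(d) for d in day_records]
    return sum(flags) >= MIN_SUFFICIENT_DAYS


def aggregate_week(daily_values: Sequence[float], sufficient_day_mask: Sequence[bool]) -> float:
    """Weekly mean of a daily feature over sufficient days.

    Returns NaN when no sufficient day carries a value — a retained week
    can still miss a specific feature.
    """
    vals = np.asarray(daily_values, dtype=float)
    mask = np.asarray(sufficient_day_mask, dtype=bool)
    if vals.shape != mask.shape:
        raise ValueError("daily values and sufficiency mask must align")
    use = mask & ~np.isnan(vals)
    if not use.any():
        return float("nan")
    return float(vals[use].mean())


def daily_sufficiency(
    minute_counts: pd.DataFrame,
    ping_hours: pd.Series,
    n_days: int,
) -> pd.DataFrame:
    """Vectorized sufficiency over a participant's whole study.

    Parameters
    ----------
    minute_counts
        day-index by sensor table of distinct sampled minutes (absent
        day/sensor combinations count as 0).
    ping_hours
        distinct app-active hours per day index.
    n_days
        total study days; days with no samples at all are insufficient.
    """
    idx = pd.RangeIndex(n_days, name="day")
    counts = minute_counts.reindex(idx, fill_value=0)
    for sensor in MINUTELY_SENSORS:
        if sensor not in counts.columns:
            counts[sensor] = 0
    counts = counts[list(MINUTELY_SENSORS)]
    hours = ping_hours.reindex(idx, fill_value=0).astype(int)
    sufficient = (counts.max(axis=1) >= MIN_MINUTES) & (hours >= MIN_ACTIVE_HOURS)
    out = counts.copy()
    out["active_hours"] = hours
    out["sufficient"] = sufficient
    return out
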