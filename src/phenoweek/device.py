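"""Device-state and activity features, and the weekly feature matrix.

Most device features are plain daily aggregates of their stream (means of
minutely levels, summed screen-on intervals, counted active minutes).
Physical-activity classification is not performed here: the activity
stream arrives with per-minute activity labels and the feature counts the
active minutes.  App usage is mapped to social / wellness / communication
categories through a packaged app->category table.

:func:`build_feature_matrix` assembles retained participant-weeks into the
canonical analysis table: exactly the 34 registry features (fixed order)
plus ``phq9_sum`` and ``depressed_week``, rows ordered by participant then
week.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .registry import FEATURE_NAMES

__all__ = [
    "load_app_categories",
    "screen_on_minutes",
    "device_daily_features",
    "build_feature_matrix",
    "META_COLUMNS",
]

META_COLUMNS = ("participant_id", "week_index", "n_sufficient_days")
APP_CATEGORIES = ("social", "wellness", "communication")


def load_app_categories() -> dict[str, str]:
    with resources.files("phenoweek.data").joinpath("app_categories.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["app"].astype(str), df["category"].astype(str)))


def screen_on_minutes(events: pd.DataFrame) -> float:
    """Summed screen-on interval minutes from on/off transition events.

    An unmatched trailing "on" is closed at the end of the day; an initial
    "off" opens an interval at the start of the day.
    """
    if not len(events):
        return 0.0
    ev = events.sort_values("timestamp")
    ts = pd.DatetimeIndex(pd.to_datetime(ev["timestamp"]))
    states = ev["state"].astype(str).to_numpy()
    day_start = ts[0].normalize()
    day_end = day_start + pd.Timedelta(days=1)
    total = 0.0
    on_since = None
    for t, s in zip(ts, states):
        if s == "on" and on_since is None:
            on_since = t
        elif s == "off":
            start = on_since if on_since is not None else day_start
            total += (t - start).total_seconds() / 60.0
            on_since = None
    if on_since is not None:
        total += (day_end - on_since).total_seconds() / 60.0
    return float(total)


def device_daily_features(
    streams: Mapping[str, pd.DataFrame | None],
    app_categories: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Daily feature values from one participant-day of device streams.

    ``streams`` maps stream name to that day's table, or ``None`` when the
    permission-gated stream produced nothing that day (``app_usage``,
    ``sleep_report``) — in which case the corresponding usage/sleep
    features are missing (NaN) and the matching indicator feature is 1.
    """
    app_categories = app_categories or load_app_categories()
    out: dict[str, float] = {}

    audio = streams.get("ambient_audio")
    out["ambient_audio_level"] = float(audio["value"].mean()) if audio is not None and len(audio) else np.nan
    light = streams.get("ambient_light")
    out["ambient_light_level"] = float(light["value"].mean()) if light is not None and len(light) else np.nan

    battery = streams.get("battery")
    if battery is not None and len(battery):
        out["battery_percentage"] = float(battery["percent"].mean())
        out["charging_minutes"] = float(np.asarray(battery["charging"], dtype=float).sum())
    else:
        out["battery_percentage"] = np.nan
        out["charging_minutes"] = np.nan

    screen = streams.get("screen")
    out["phone_screen_on_minutes"] = screen_on_minutes(screen) if screen is not None and len(screen) else np.nan

    volume = streams.get("volume")
    for channel, name in (
        ("system", "audio_system_volume"),
        ("ring", "ring_volume"),
        ("notification", "audio_notification_volume"),
    ):
        if volume is not None and len(volume):
            sel = volume[volume["channel"] == channel]
            out[name] = float(sel["level"].mean()) if len(sel) else np.nan
        else:
            out[name] = np.nan

    wifi = streams.get("wifi")
    if wifi is not None and len(wifi):
        out["n_wifi_networks"] = float(wifi["ssid"].nunique())
        out["nearby_wifi_count"] = float(wifi["n_nearby"].mean())
    else:
        out["n_wifi_networks"] = np.nan
        out["nearby_wifi_count"] = np.nan

    activity = streams.get("activity")
    out["physically_active_minutes"] = (
        float(np.asarray(activity["value"], dtype=float).sum()) if activity is not None and len(activity) else np.nan
    )

    apps = streams.get("app_usage")
    if apps is not None and len(apps):
        out["app_usage_missing"] = 0.0
        cats = apps["app"].map(lambda a: app_categories.get(str(a), "other"))
        sums = apps.groupby(cats.to_numpy())["minutes"].sum()
        for cat in APP_CATEGORIES:
            out[f"{cat}_apps_usage"] = float(sums.get(cat, 0.0))
    else:
        out["app_usage_missing"] = 1.0
        for cat in APP_CATEGORIES:
            out[f"{cat}_apps_usage"] = np.nan

    sleep = streams.get("sleep_report")
    if sleep is not None and len(sleep):
        out["reported_sleep_duration_missing"] = 0.0
        out["reported_sleep_duration"] = float(sleep["hours"].mean())
    else:
        out["reported_sleep_duration_missing"] = 1.0
        out["reported_sleep_duration"] = np.nan

    return out


def build_feature_matrix(weeks: Iterable[Mapping]) -> pd.DataFrame:
    """Assemble retained participant-weeks into the canonical table.

    Each element provides ``participant_id``, ``week_index``, optionally
    ``n_sufficient_days``, a ``features`` mapping restricted to registry
    names, and ``phq9_sum`` (None/NaN when the survey is missing).
    ``depressed_week`` is the PHQ-9 >= 10 dichotomization.
    """
    rows = []
    for wk in weeks:
        feats = dict(wk.get("features", {}))
        unknown = set(feats) - set(FEATURE_NAMES)
        if unknown:
            raise KeyError(f"unknown feature name(s): {sorted(unknown)}")
        row = {
            "participant_id": wk["participant_id"],
            "week_index": int(wk["week_index"]),
            "n_sufficient_days": int(wk.get("n_sufficient_days", 0)),
        }
        for name in FEATURE_NAMES:
            row[name] = feats.get(name, np.nan)
        phq = wk.get("phq9_sum")
        row["phq9_sum"] = np.nan if phq is None else float(phq)
        rows.append(row)
    cols = list(META_COLUMNS) + list(FEATURE_NAMES) + ["phq9_sum"]
    df = pd.DataFrame(rows, columns=cols)
    df["depressed_week"] = np.where(
        df["phq9_sum"].isna(), np.nan, (df["phq9_sum"] >= 10).astype(float)
    )
    df = df.sort_values(["participant_id", "week_index"], kind="stable").reset_index(drop=True)
    return df
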