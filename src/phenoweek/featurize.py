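"""Raw sensor streams -> retained participant-weeks with 34 features.

The path per participant: assess every study day for data sufficiency
(720 distinct minutes on some minutely sensor, 18 app-active hours),
retain weeks with >= 3 sufficient days, compute daily feature values,
average them over the week's sufficient days, and attach the weekly
diary, location and PHQ-9 results.  Event-driven features (calls, texts)
are 0 on sufficient days without events; permission-gated streams
(app usage, sleep report) are missing -- not zero -- when absent, mirrored
by the two missingness indicator features.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import CohortConfig, LocationConfig, MINUTELY_SENSORS
from .device import build_feature_matrix, load_app_categories
from .diary_comms import count_emoji, diary_features, load_lexicon
from .filtering import MIN_SUFFICIENT_DAYS, aggregate_week, daily_sufficiency
from .location import (
    cluster_centroids,
    cluster_locations,
    cluster_place_tags,
    label_home,
    location_entropy,
    location_variance,
)
from .registry import FEATURE_NAMES
from .simulate import StudyData, iter_participants

__all__ = ["featurize_participant", "featurize_study", "featurize_cohort"]

def _day_index(ts, start: pd.Timestamp) -> np.ndarray:
    idx = pd.DatetimeIndex(pd.to_datetime(ts))
    return ((idx.normalize() - start).days).to_numpy()


def _date_day_index(dates, start: pd.Timestamp) -> np.ndarray:
    idx = pd.DatetimeIndex(pd.to_datetime(dates))
    return ((idx - start).days).to_numpy()


def _screen_daily_minutes(scr: pd.DataFrame, start: pd.Timestamp, n_days: int) -> pd.Series:
    """Daily screen-on minutes from on/off events, split at midnight.

    Equivalent to running :func:`phenoweek.device.screen_on_minutes` on
    each day's events; days with no events at all stay missing.
    """
    ts = pd.DatetimeIndex(pd.to_datetime(scr["timestamp"]))
    order = np.argsort(ts.asi8, kind="stable")
    t_min = (ts.asi8[order] - start.value) / 60e9  # minutes since study start
    states = scr["state"].astype(str).to_numpy()[order]
    out = np.zeros(n_days)
    seen = np.zeros(n_days, dtype=bool)
    day_of = (t_min // 1440).astype(int)
    ok = (day_of >= 0) & (day_of < n_days)
    seen[np.unique(day_of[ok])] = True
    on_since: float | None = None

    def credit(a: float, b: float) -> None:
        da, db = int(a // 1440), int(b // 1440)
        while da < db:
            boundary = (da + 1) * 1440.0
            if 0 <= da < n_days:
                out[da] += boundary - a
            a, da = boundary, da + 1
        if 0 <= da < n_days:
            out[da] += b - a

    for t, s in zip(t_min, states):
        if s == "on":
            if on_since is None:
                on_since = t
        elif on_since is not None:
            credit(on_since, t)
            on_since = None
        else:  # unmatched off: on since that day's start
            credit((t // 1440) * 1440.0, t)
    if on_since is not None:  # trailing on: close at end of its day
        credit(on_since, (int(on_since // 1440) + 1) * 1440.0)
    return pd.Series(np.where(seen, out, np.nan), index=pd.RangeIndex(n_days, name="day"))


def _daily_mean(df: pd.DataFrame | None, col: str, start, n_days) -> pd.Series:
    out = pd.Series(np.nan, index=pd.RangeIndex(n_days, name="day"))
    if df is None or not len(df):
        return out
    day = _day_index(df["timestamp"], start)
    grp = pd.Series(df[col].to_numpy(), index=day).groupby(level=0).mean()
    out.update(grp)
    return out


def featurize_participant(
    streams: Mapping[str, pd.DataFrame],
    enrollment: pd.Timestamp,
    n_weeks: int,
    place_tags: pd.DataFrame | None = None,
    loc_cfg: LocationConfig | None = None,
    app_categories: Mapping[str, str] | None = None,
    lexicon: Mapping[str, float] | None = None,
    participant_id: str = "",
) -> list[dict]:
    """Weekly records for one participant (only retained weeks).

    ``streams`` maps stream name to that participant's raw table; an
    absent or empty stream yields missing values for its features.
    """
    loc_cfg = loc_cfg or LocationConfig()
    loc_cfg.validate()
    app_categories = app_categories or load_app_categories()
    lexicon = lexicon if lexicon is not None else load_lexicon()
    start = pd.Timestamp(enrollment)
    n_days = n_weeks * 7
    days = pd.RangeIndex(n_days, name="day")
    week_of_day = np.arange(n_days) // 7

    def stream(name: str) -> pd.DataFrame | None:
        df = streams.get(name)
        return df if df is not None and len(df) else None

    # --- sufficiency ---------------------------------------------------------
    minute_counts = pd.DataFrame(index=days)
    ping_hours = pd.Series(0, index=days)
    for sensor in MINUTELY_SENSORS:
        df = stream(sensor) if sensor != "location" else stream("location")
        if df is None:
            minute_counts[sensor] = 0
            continue
        ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
        day = ((ts.normalize() - start).days).to_numpy()
        minute_key = day.astype(np.int64) * 1440 + (ts.hour * 60 + ts.minute).to_numpy()
        uniq = np.unique(minute_key)
        counts = pd.Series(1, index=uniq // 1440).groupby(level=0).sum()
        minute_counts[sensor] = counts.reindex(days, fill_value=0)
        if sensor == "ping":
            hour_key = np.unique(day.astype(np.int64) * 24 + ts.hour.to_numpy())
            ping_hours = (
                pd.Series(1, index=hour_key // 24).groupby(level=0).sum().reindex(days, fill_value=0)
            )
    suff = daily_sufficiency(minute_counts.fillna(0), ping_hours, n_days)
    suff_mask = suff["sufficient"].to_numpy(dtype=bool)
    week_suff_days = pd.Series(suff_mask).groupby(week_of_day).sum()
    retained_weeks = week_suff_days[week_suff_days >= MIN_SUFFICIENT_DAYS].index.to_numpy()

    if retained_weeks.size == 0:
        return []

    # --- daily feature table -------------------------------------------------
    daily = pd.DataFrame(index=days, columns=list(FEATURE_NAMES), dtype=float)

    daily["ambient_audio_level"] = _daily_mean(stream("ambient_audio"), "value", start, n_days)
    daily["ambient_light_level"] = _daily_mean(stream("ambient_light"), "value", start, n_days)

    act = stream("activity")
    if act is not None:
        day = _day_index(act["timestamp"], start)
        daily["physically_active_minutes"] = (
            pd.Series(act["value"].to_numpy(dtype=float), index=day).groupby(level=0).sum().reindex(days)
        )

    batt = stream("battery")
    if batt is not None:
        day = _day_index(batt["timestamp"], start)
        daily["battery_percentage"] = (
            pd.Series(batt["percent"].to_numpy(dtype=float), index=day).groupby(level=0).mean().reindex(days)
        )
        daily["charging_minutes"] = (
            pd.Series(batt["charging"].to_numpy(dtype=float), index=day).groupby(level=0).sum().reindex(days)
        )

    scr = stream("screen")
    if scr is not None:
        daily["phone_screen_on_minutes"] = _screen_daily_minutes(scr, start, n_days)

    vol = stream("volume")
    if vol is not None:
        day = _date_day_index(vol["date"], start)
        piv = vol.assign(_day=day).pivot_table(index="_day", columns="channel", values="level", aggfunc="mean")
        for channel, feat in (
            ("system", "audio_system_volume"),
            ("ring", "ring_volume"),
            ("notification", "audio_notification_volume"),
        ):
            if channel in piv.columns:
                daily[feat] = piv[channel].reindex(days)

    wifi = stream("wifi")
    if wifi is not None:
        day = _day_index(wifi["timestamp"], start)
        g = wifi.assign(_day=day).groupby("_day")
        daily["n_wifi_networks"] = g["ssid"].nunique().astype(float).reindex(days)
        daily["nearby_wifi_count"] = g["n_nearby"].mean().reindex(days)

    apps = stream("app_usage")
    if apps is not None:
        day = _date_day_index(apps["date"], start)
        cats = apps["app"].map(lambda a: app_categories.get(str(a), "other"))
        tab = (
            apps.assign(_day=day, _cat=cats.to_numpy())
            .pivot_table(index="_day", columns="_cat", values="minutes", aggfunc="sum")
            .reindex(days)
        )
        present = tab.notna().any(axis=1)
        for cat in ("social", "wellness", "communication"):
            col = tab[cat] if cat in tab.columns else pd.Series(np.nan, index=days)
            daily[f"{cat}_apps_usage"] = col.where(~present, col.fillna(0.0))
        daily["app_usage_missing"] = (~present).astype(float)
    else:
        daily["app_usage_missing"] = 1.0

    sleep = stream("sleep_report")
    if sleep is not None:
        day = _date_day_index(sleep["date"], start)
        vals = pd.Series(sleep["hours"].to_numpy(dtype=float), index=day).groupby(level=0).mean().reindex(days)
        daily["reported_sleep_duration"] = vals
        daily["reported_sleep_duration_missing"] = vals.isna().astype(float)
    else:
        daily["reported_sleep_duration_missing"] = 1.0

    calls = stream("calls")
    if calls is not None:
        # vectorized equivalent of the per-day call_features aggregation;
        # a kept day with no calls is a 0, not missing
        day = _day_index(calls["timestamp"], start)
        incoming = calls["direction"].to_numpy() == "incoming"
        answered = calls["outcome"].to_numpy() == "answered"
        dur = calls["duration_s"].to_numpy(dtype=float)
        ring = calls["ring_s"].to_numpy(dtype=float)
        tab = (
            pd.DataFrame(
                {
                    "phone_call_count": 1.0,
                    "incoming_phone_call_duration": np.where(incoming & answered, dur, 0.0),
                    "outgoing_phone_call_duration": np.where(~incoming & answered, dur, 0.0),
                    "ring_until_missed_minutes": np.where(incoming & ~answered, ring / 60.0, 0.0),
                },
                index=day,
            )
            .groupby(level=0)
            .sum()
            .reindex(days)
        )
        for feat in tab.columns:
            daily[feat] = tab[feat].fillna(0.0)

    texts = stream("texts")
    if texts is not None:
        # per-message emoji/body/lexicon sums, then daily totals; daily
        # sentiment = total in-lexicon score / total in-lexicon tokens,
        # identical to scoring the day's concatenated outgoing tokens
        tx = texts[texts["direction"] == "outgoing"]
        for feat in ("text_message_count", "text_message_emoji_count", "text_message_body_size", "outgoing_text_sentiment"):
            daily[feat] = 0.0
        if len(tx):
            day = _day_index(tx["timestamp"], start)
            bodies = [str(b) for b in tx["body"]]
            score_sum = np.empty(len(bodies))
            n_inlex = np.empty(len(bodies))
            for i, b in enumerate(bodies):
                scores = [lexicon[t] for t in b.split() if t in lexicon]
                score_sum[i] = sum(scores)
                n_inlex[i] = len(scores)
            tab = (
                pd.DataFrame(
                    {
                        "text_message_count": 1.0,
                        "text_message_emoji_count": [float(count_emoji(b)) for b in bodies],
                        "text_message_body_size": [float(len(b)) for b in bodies],
                        "_score": score_sum,
                        "_n": n_inlex,
                    },
                    index=day,
                )
                .groupby(level=0)
                .sum()
                .reindex(days)
            )
            for feat in ("text_message_count", "text_message_emoji_count", "text_message_body_size"):
                daily[feat] = tab[feat].fillna(0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sent = np.where(tab["_n"].to_numpy() > 0, tab["_score"].to_numpy() / tab["_n"].to_numpy(), 0.0)
            daily["outgoing_text_sentiment"] = np.nan_to_num(sent, nan=0.0)

    # --- location family -----------------------------------------------------
    loc = stream("location")
    loc_week: dict[int, dict[str, float]] = {}
    if loc is not None:
        lat = loc["lat"].to_numpy(dtype=float)
        lon = loc["lon"].to_numpy(dtype=float)
        ts = pd.DatetimeIndex(pd.to_datetime(loc["timestamp"]))
        day = ((ts.normalize() - start).days).to_numpy()
        labels = cluster_locations(
            lat, lon, eps_m=loc_cfg.eps_m, min_samples=loc_cfg.min_samples, grid_m=loc_cfg.grid_m
        )
        home = label_home(labels, ts)
        centroids = cluster_centroids(lat, lon, labels)
        tag_table = place_tags if place_tags is not None else pd.DataFrame(columns=["lat", "lon", "tags"])
        if "participant_id" in tag_table.columns and participant_id:
            tag_table = tag_table[tag_table["participant_id"] == participant_id]
        tags = cluster_place_tags(centroids, tag_table)
        hospital_ids = {c for c, t in tags.items() if "hospital or doctor's office" in t}

        ok = (day >= 0) & (day < n_days) & suff_mask[np.clip(day, 0, n_days - 1)]
        week = np.where(ok, day // 7, -1)
        home_daily = pd.Series(
            ((labels == home) & ok).astype(float) if home is not None else np.zeros(len(labels)),
            index=day,
        ).groupby(level=0).sum().reindex(days, fill_value=0.0)
        hosp_daily = pd.Series(
            (np.isin(labels, sorted(hospital_ids)) & ok).astype(float), index=day
        ).groupby(level=0).sum().reindex(days, fill_value=0.0)
        daily["time_spent_at_home"] = home_daily
        daily["time_spent_at_hospital"] = hosp_daily

        for w in retained_weeks:
            in_w = week == w
            if not in_w.any():
                continue
            lab_w = labels[in_w]
            clustered = lab_w >= 0
            feats: dict[str, float] = {}
            uniq = np.unique(lab_w[clustered])
            feats["unique_location_clusters"] = float(uniq.size)
            if uniq.size:
                minutes = pd.Series(lab_w[clustered]).value_counts().to_numpy()
                feats["location_entropy"] = location_entropy(minutes)
            feats["location_variance"] = location_variance(lat[in_w], lon[in_w])
            loc_week[int(w)] = feats

    # --- weekly assembly -----------------------------------------------------
    diary = stream("diary")
    diary_by_week = {}
    if diary is not None:
        for rec in diary.itertuples():
            pauses = [float(p) for p in str(rec.pauses_s).split(";") if p not in ("", "nan")]
            feats = diary_features(str(rec.transcript).split(), float(rec.duration_s), pauses, lexicon)
            diary_by_week[int(rec.week_index)] = {
                "voice_diary_sentiment": feats.sentiment,
                "voice_diary_words_per_minute": feats.words_per_minute,
                "voice_diary_duration": feats.duration_s,
                "voice_diary_pauses_duration": feats.mean_pause_s,
            }

    phq = stream("phq9")
    phq_by_week = (
        {int(r.week_index): float(r.phq9_sum) for r in phq.itertuples()} if phq is not None else {}
    )

    daily_mat = daily.to_numpy(dtype=float)
    col_idx = {name: i for i, name in enumerate(daily.columns)}
    weekly_cols = set().union(*(set(d) for d in loc_week.values())) if loc_week else set()
    weekly_cols |= {
        "voice_diary_sentiment",
        "voice_diary_words_per_minute",
        "voice_diary_duration",
        "voice_diary_pauses_duration",
    }
    records = []
    for w in retained_weeks:
        sl = slice(w * 7, w * 7 + 7)
        mask = suff_mask[sl]
        feats: dict[str, float] = {}
        for name in FEATURE_NAMES:
            if name in weekly_cols:
                continue
            feats[name] = aggregate_week(daily_mat[sl, col_idx[name]], mask)
        feats.update(loc_week.get(int(w), {}))
        feats.update(diary_by_week.get(int(w), {}))
        records.append(
            {
                "participant_id": participant_id,
                "week_index": int(w),
                "n_sufficient_days": int(mask.sum()),
                "features": feats,
                "phq9_sum": phq_by_week.get(int(w)),
            }
        )
    return records


def featurize_study(data: StudyData, loc_cfg: LocationConfig | None = None) -> pd.DataFrame:
    """Feature matrix for a materialized study dataset."""
    app_categories = load_app_categories()
    lexicon = load_lexicon()
    records: list[dict] = []
    n_weeks = None
    for row in data.participants.itertuples():
        pid = row.participant_id
        streams = {
            name: df[df["participant_id"] == pid]
            for name, df in data.streams.items()
        }
        if n_weeks is None:
            phq = data.streams.get("phq9")
            # study length from the data: last possible week index + 1
            n_weeks = 12
            ts_max = max(
                (pd.to_datetime(df["timestamp"]).max() for df in data.streams.values() if "timestamp" in df.columns and len(df)),
                default=None,
            )
            if ts_max is not None:
                n_weeks = int(((ts_max - pd.Timestamp(row.enrollment_date)).days // 7) + 1)
        records.extend(
            featurize_participant(
                streams,
                enrollment=row.enrollment_date,
                n_weeks=n_weeks,
                place_tags=data.place_tags,
                loc_cfg=loc_cfg,
                app_categories=app_categories,
                lexicon=lexicon,
                participant_id=pid,
            )
        )
    return build_feature_matrix(records)


def featurize_cohort(cfg: CohortConfig, loc_cfg: LocationConfig | None = None) -> pd.DataFrame:
    """Simulate and featurize in one streaming pass (memory-light).

    Equivalent to ``featurize_study(generate_cohort(cfg))`` but holds a
    single participant's raw streams at a time.
    """
    app_categories = load_app_categories()
    lexicon = load_lexicon()
    records: list[dict] = []
    for pdata in iter_participants(cfg):
        records.extend(
            featurize_participant(
                pdata.streams,
                enrollment=cfg.start_date,
                n_weeks=cfg.n_weeks,
                place_tags=pdata.place_tags,
                loc_cfg=loc_cfg,
                app_categories=app_categories,
                lexicon=lexicon,
                participant_id=pdata.participant_id,
            )
        )
    return build_feature_matrix(records)
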