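"""Synthetic multi-sensor smartphone cohort generator.

Emulates a fully remote 12-week observational study: a cohort with an
80:20 depressed:nondepressed recruitment split, a weekly latent severity
process per participant, minutely passive sensor streams, user-driven
event logs (calls, texts, screen, app usage), weekly voice diaries and
PHQ-9 surveys, and realistic missing-data regimes (whole-sensor absence,
day dropout, per-minute loss, skipped surveys).

Model
-----
Latent severity follows an AR(1) weekly process in the logit units of a
binomial item-response model: participant baseline ~ N(mu_arm, between_sd),
weekly deviations x_w = phi * x_{w-1} + eps.  The arm means mu_arm are
calibrated numerically so the expected baseline PHQ-9 sum is 17.4 in the
depressed arm and 5.4 in the control arm.  Each PHQ-9 item is
Binomial(3, logistic(severity + item offset)), which respects the 0-3 item
range and gives a mean sum monotone in severity.

Each behavioral feature f has a signed standardized effect e_f.  The
weekly generating target for f is ``base + scale * z`` with
``z = e_f * severity_z + 0.6 * b_participant + 0.6 * noise_week``; streams
are then realized so their daily aggregates recover the target on
average.  Location effects are mechanistic: severity lowers the outing
rate, raises work-skipping and lowers hospital visits, which jointly move
homestay, unique clusters, entropy and variance with the configured signs.

Two fidelity levels are exposed: :func:`generate_cohort` /
:func:`iter_participants` realize the full minutely dataset, while
:func:`simulate_feature_matrix` draws the 34 weekly features directly
from the same weekly target model (for replicate-heavy statistical
checks).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import (
    CohortConfig,
    ConfigError,
    MINUTELY_SENSORS,
    severity_mixture_stats,
)
from .diary_comms import load_lexicon
from .registry import FEATURE_NAMES, INDICATOR_FEATURES

__all__ = [
    "Phq9Response",
    "ParticipantData",
    "StudyData",
    "severity_to_phq9",
    "calibrate_arm_means",
    "simulate_severity",
    "generate_daily_trajectory",
    "generate_participant",
    "iter_participants",
    "generate_cohort",
    "simulate_feature_matrix",
]

# ---------------------------------------------------------------------------
# PHQ-9 item-response model

PHQ9_ITEM_OFFSETS = np.linspace(-1.2, 1.2, 9)
BASELINE_SUM_DEPRESSED = 17.4
BASELINE_SUM_CONTROL = 5.4


@dataclass
class Phq9Response:
    participant_id: str
    week_index: int
    items: np.ndarray

    @property
    def sum(self) -> int:
        return int(np.sum(self.items))


def severity_to_phq9(severity: float, rng: np.random.Generator) -> np.ndarray:
    """Draw nine PHQ-9 item scores (0-3) from the item-response model.

    Expected sum is monotone increasing in ``severity``; the infinite
    limits hit the scale floor (all 0) and ceiling (all 3) exactly.
    """
    p = expit(severity + PHQ9_ITEM_OFFSETS)
    return rng.binomial(3, p).astype(int)


def _expected_phq9_sum(mu: float, sd: float) -> float:
    """E[PHQ-9 sum] when severity ~ N(mu, sd^2) (Gauss-Hermite, 61 nodes)."""
    x, w = np.polynomial.hermite.hermgauss(61)
    sev = mu + math.sqrt(2.0) * sd * x[:, None]
    means = 3.0 * expit(sev + PHQ9_ITEM_OFFSETS[None, :]).sum(axis=1)
    return float((w * means).sum() / math.sqrt(math.pi))


@functools.lru_cache(maxsize=32)
def calibrate_arm_means(severity_sd: float) -> tuple[float, float]:
    """Arm means (depressed, control) hitting the baseline PHQ-9 targets.

    ``severity_sd`` is the week-0 severity SD (between-participant plus
    stationary AR(1) spread).  Solved by root finding on the exact
    expectation; deterministic and cached.
    """
    sd = float(severity_sd)

    def solve(target: float) -> float:
        return brentq(lambda mu: _expected_phq9_sum(mu, sd) - target, -8.0, 8.0, xtol=1e-10)

    return solve(BASELINE_SUM_DEPRESSED), solve(BASELINE_SUM_CONTROL)


def _severity_sd(cfg: CohortConfig) -> float:
    return math.sqrt(cfg.between_sd**2 + cfg.innovation_sd**2 / (1.0 - cfg.persistence**2))


def simulate_severity(rng: np.random.Generator, arm_mu: float, cfg: CohortConfig) -> np.ndarray:
    """AR(1) weekly severity trajectory around a participant baseline."""
    base = arm_mu + rng.normal(0.0, cfg.between_sd)
    sd_stat = cfg.innovation_sd / math.sqrt(1.0 - cfg.persistence**2)
    x = np.empty(cfg.n_weeks)
    x[0] = rng.normal(0.0, sd_stat)
    for w in range(1, cfg.n_weeks):
        x[w] = cfg.persistence * x[w - 1] + rng.normal(0.0, cfg.innovation_sd)
    return base + x


# ---------------------------------------------------------------------------
# Weekly feature target model (shared by both fidelity levels)

# per-feature (base, scale, lower clip, upper clip) on the weekly scale
FEATURE_GEN: dict[str, tuple[float, float, float, float]] = {
    "voice_diary_sentiment": (0.18, 0.35, -1.0, 1.0),
    "reported_sleep_duration": (7.0, 0.9, 1.0, 14.0),
    "ambient_audio_level": (45.0, 6.0, 0.0, np.inf),
    "ring_until_missed_minutes": (0.5, 0.3, 0.0, np.inf),
    "unique_location_clusters": (6.0, 1.5, 1.0, np.inf),
    "voice_diary_words_per_minute": (110.0, 15.0, 30.0, 220.0),
    "voice_diary_duration": (95.0, 30.0, 15.0, 900.0),
    "battery_percentage": (58.0, 8.0, 1.0, 100.0),
    "text_message_emoji_count": (3.0, 1.5, 0.0, np.inf),
    "phone_call_count": (2.2, 0.8, 0.0, np.inf),
    "voice_diary_pauses_duration": (1.3, 0.4, 0.0, 30.0),
    "location_entropy": (1.1, 0.3, 0.0, np.inf),
    "ambient_light_level": (110.0, 25.0, 0.0, np.inf),
    "outgoing_text_sentiment": (0.15, 0.3, -1.0, 1.0),
    "location_variance": (8e-4, 3e-4, 0.0, np.inf),
    "phone_screen_on_minutes": (170.0, 40.0, 5.0, 1200.0),
    "audio_system_volume": (0.55, 0.13, 0.0, 1.0),
    "charging_minutes": (95.0, 25.0, 5.0, 700.0),
    "social_apps_usage": (70.0, 22.0, 0.0, np.inf),
    "time_spent_at_home": (950.0, 120.0, 0.0, 1440.0),
    "app_usage_missing": (0.1, 0.0, 0.0, 1.0),
    "outgoing_phone_call_duration": (180.0, 60.0, 0.0, np.inf),
    "wellness_apps_usage": (12.0, 5.0, 0.0, np.inf),
    "time_spent_at_hospital": (7.0, 4.0, 0.0, np.inf),
    "n_wifi_networks": (4.5, 1.2, 1.0, np.inf),
    "reported_sleep_duration_missing": (0.15, 0.0, 0.0, 1.0),
    "communication_apps_usage": (30.0, 9.0, 0.0, np.inf),
    "text_message_body_size": (220.0, 60.0, 0.0, np.inf),
    "ring_volume": (0.5, 0.13, 0.0, 1.0),
    "physically_active_minutes": (35.0, 12.0, 0.0, 600.0),
    "audio_notification_volume": (0.5, 0.13, 0.0, 1.0),
    "text_message_count": (3.2, 1.0, 0.0, np.inf),
    "nearby_wifi_count": (6.0, 1.8, 0.0, np.inf),
    "incoming_phone_call_duration": (200.0, 60.0, 0.0, np.inf),
}

_B_NOISE = 0.6  # participant-level channel noise SD
_W_NOISE = 0.6  # week-level channel noise SD


def weekly_targets(
    rng: np.random.Generator,
    severity_z: np.ndarray,
    effects: dict[str, float],
) -> pd.DataFrame:
    """Weekly generating targets for every registered feature.

    Row per study week, column per feature; the configured signed effect
    of standardized severity enters each feature's latent channel.
    """
    n_weeks = len(severity_z)
    cols = {}
    for name in FEATURE_NAMES:
        base, scale, lo, hi = FEATURE_GEN[name]
        eff = effects.get(name, 0.0)
        b = rng.normal(0.0, 1.0)
        e = rng.normal(0.0, 1.0, size=n_weeks)
        z = eff * severity_z + _B_NOISE * b + _W_NOISE * e
        cols[name] = np.clip(base + scale * z, lo, hi)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# GPS trajectories

M_PER_DEG_LAT = 111_320.0
_TRANSIT_JITTER_M = 400.0  # GPS error while moving (urban-canyon scale)
_ROUTE_SPREAD_M = 500.0  # day-to-day route variation between fixed places

# anchor roles and synthetic semantic tags
ANCHOR_TAGS = (
    "residential",
    "office",
    "hospital or doctor's office",
    "place to exercise",
    "grocery or supermarket",
    "restaurant or cafe",
    "park",
    "other",
)
_HOSPITAL_ANCHOR = 2


def _haversine_m(lat1, lon1, lat2, lon2) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    a = math.sin((p2 - p1) / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * 6_371_000.0 * math.asin(math.sqrt(a))


def _make_anchors(rng: np.random.Generator) -> np.ndarray:
    """Eight anchor (lat, lon) points: home, work, and six other places."""
    home = np.array([40.0 + rng.uniform(-0.3, 0.3), -75.0 + rng.uniform(-0.3, 0.3)])
    anchors = [home]
    dists = [0.0, rng.uniform(1500, 5000)] + list(rng.uniform(500, 8000, size=6))
    for d in dists[1:]:
        bearing = rng.uniform(0, 2 * math.pi)
        dlat = d * math.cos(bearing) / M_PER_DEG_LAT
        dlon = d * math.sin(bearing) / (M_PER_DEG_LAT * math.cos(math.radians(home[0])))
        anchors.append(home + [dlat, dlon])
    return np.asarray(anchors)


def _schedule_day(
    rng: np.random.Generator,
    workday: bool,
    work_today: bool,
    lam_outings: float,
    outings_dest: np.ndarray,
    hospital_today: bool,
):
    """Per-minute anchor schedule for one day.

    Returns (anchor index per minute, transit fraction (NaN off-transit),
    transit origin, transit destination).  Nights (11 PM-4 AM) are at
    home by construction; a workday with work keeps the 10 AM-3 PM window
    at the work anchor.
    """
    state = np.zeros(1440, dtype=int)
    frac = np.full(1440, np.nan)
    t_from = np.zeros(1440, dtype=int)
    t_to = np.zeros(1440, dtype=int)
    t_seg = np.zeros(1440, dtype=int)
    seg_counter = [0]

    def set_transit(a: int, b: int, start: int, dur: int) -> None:
        end = min(start + dur, 1440)
        if end <= start:
            return
        seg_counter[0] += 1
        idx = np.arange(start, end)
        state[idx] = -1
        frac[idx] = (idx - start + 0.5) / dur
        t_from[idx] = a
        t_to[idx] = b
        t_seg[idx] = seg_counter[0]

    busy = np.zeros(1440, dtype=bool)
    busy[: 4 * 60] = True
    busy[23 * 60 :] = True

    if workday and work_today:
        depart = int(rng.integers(9 * 60 + 15, 9 * 60 + 45))
        tdur = int(np.clip(rng.normal(12, 3), 6, 25))
        ret = int(rng.integers(16 * 60 + 30, 17 * 60 + 10))
        tdur2 = int(np.clip(rng.normal(12, 3), 6, 25))
        state[depart + tdur : ret] = 1
        set_transit(0, 1, depart, tdur)
        set_transit(1, 0, ret, tdur2)
        busy[depart : min(ret + tdur2, 1440)] = True

    visits: list[tuple[int, int]] = []  # (dest, duration)
    if hospital_today:
        visits.append((_HOSPITAL_ANCHOR, int(np.clip(rng.normal(50, 10), 25, 120))))
    for _ in range(rng.poisson(lam_outings)):
        dest = int(rng.choice(outings_dest))
        visits.append((dest, int(np.clip(rng.normal(60, 18), 20, 150))))

    window_lo = 16 * 60 + 30 if (workday and work_today) else 9 * 60 + 30
    window_hi = 22 * 60
    for dest, dur in visits:
        span = dur + 12
        if window_hi - window_lo <= span:
            continue
        for _attempt in range(4):
            start = int(rng.integers(window_lo, window_hi - span))
            if not busy[start : start + span].any():
                set_transit(0, dest, start, 6)
                state[start + 6 : start + 6 + dur] = dest
                set_transit(dest, 0, start + 6 + dur, 6)
                busy[start : start + span] = True
                break

    # nights pinned at home
    state[: 4 * 60] = 0
    frac[: 4 * 60] = np.nan
    state[23 * 60 :] = 0
    frac[23 * 60 :] = np.nan
    return state, frac, t_from, t_to, t_seg


def _positions(
    rng: np.random.Generator,
    anchors: np.ndarray,
    state: np.ndarray,
    frac: np.ndarray,
    t_from: np.ndarray,
    t_to: np.ndarray,
    t_seg: np.ndarray,
    jitter_m: float,
) -> tuple[np.ndarray, np.ndarray]:
    lat = anchors[np.maximum(state, 0), 0].copy()
    lon = anchors[np.maximum(state, 0), 1].copy()
    transit = state < 0
    if transit.any():
        f = frac[transit]
        a_lat = anchors[t_from[transit], 0]
        a_lon = anchors[t_from[transit], 1]
        b_lat = anchors[t_to[transit], 0]
        b_lon = anchors[t_to[transit], 1]
        lat_t = a_lat + f * (b_lat - a_lat)
        lon_t = a_lon + f * (b_lon - a_lon)
        # per-transit route variation: a random midpoint offset, pinned at
        # the endpoints, so repeated trips never overlap densely
        coslat0 = np.cos(np.radians(np.mean(anchors[:, 0])))
        for seg in np.unique(t_seg[transit]):
            off_lat = rng.normal(0.0, _ROUTE_SPREAD_M) / M_PER_DEG_LAT
            off_lon = rng.normal(0.0, _ROUTE_SPREAD_M) / (M_PER_DEG_LAT * coslat0)
            sel = t_seg[transit] == seg
            bow = np.sin(np.pi * f[sel])
            lat_t[sel] += off_lat * bow
            lon_t[sel] += off_lon * bow
        lat[transit] = lat_t
        lon[transit] = lon_t
    sigma = np.where(transit, _TRANSIT_JITTER_M, jitter_m)
    coslat = np.cos(np.radians(np.mean(anchors[:, 0])))
    lat = lat + rng.normal(0.0, 1.0, lat.size) * sigma / M_PER_DEG_LAT
    lon = lon + rng.normal(0.0, 1.0, lon.size) * sigma / (M_PER_DEG_LAT * coslat)
    return lat, lon


def generate_daily_trajectory(
    rng: np.random.Generator,
    home_anchor,
    work_anchor,
    severity_z: float = 0.0,
    workday: bool = True,
    work_today: bool | None = None,
    jitter_m: float = 10.0,
    other_anchors=None,
    outing_rate: float = 1.1,
    outing_severity_gain: float = -0.9,
) -> pd.DataFrame:
    """One day of minutely positions around home/work/other anchors.

    Construction guarantees: 11 PM-4 AM at home; on a workday with work
    attendance the work anchor occupies the whole 10 AM-3 PM window (well
    above the 15% labeling threshold).  Higher severity lowers the outing
    rate, raising the homestay fraction.
    """
    home = np.asarray(home_anchor, float)
    work = np.asarray(work_anchor, float)
    if _haversine_m(home[0], home[1], work[0], work[1]) < 500.0:
        raise ConfigError("home and work anchors must be at least 500 m apart")
    if other_anchors is None:
        anchors = np.vstack([home, work])
        dest = np.array([1])  # no other places: outings disabled below
        lam = 0.0
    else:
        anchors = np.vstack([home, work, np.asarray(other_anchors, float)])
        dest = np.arange(2, len(anchors))
        lam = outing_rate * math.exp(outing_severity_gain * severity_z)
    state, frac, t_from, t_to, t_seg = _schedule_day(
        rng, workday, work_today if work_today is not None else workday, lam, dest, False
    )
    lat, lon = _positions(rng, anchors, state, frac, t_from, t_to, t_seg, jitter_m)
    return pd.DataFrame({"minute": np.arange(1440), "lat": lat, "lon": lon, "anchor": state})


# ---------------------------------------------------------------------------
# Full participant generation

_EMOJI_POOL = ["\U0001F600", "\U0001F60A", "\U0001F62D", "\U0001F44D", "❤", "\U0001F389"]
_FILLER_TOKENS = (
    "i the and week today work home day really just felt feel was been my it "
    "a to of this that with have had going things time week about more some"
).split()


@dataclass
class ParticipantData:
    participant_id: str
    arm: str
    severity: np.ndarray
    streams: dict[str, pd.DataFrame] = field(default_factory=dict)
    place_tags: pd.DataFrame | None = None


@dataclass
class StudyData:
    """A full synthetic study: participant roster plus one table per stream."""

    participants: pd.DataFrame
    streams: dict[str, pd.DataFrame]
    place_tags: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.place_tags.to_csv(out / "place_tags.csv", index=False)
        for name, df in sorted(self.streams.items()):
            df.to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def read(cls, indir) -> "StudyData":
        from pathlib import Path

        ind = Path(indir)
        participants = pd.read_csv(ind / "participants.csv")
        place_tags = pd.read_csv(ind / "place_tags.csv")
        streams = {}
        for path in sorted(ind.glob("*.csv")):
            if path.stem in ("participants", "place_tags"):
                continue
            df = pd.read_csv(path)
            if "timestamp" in df.columns:
                df["timestamp"] = pd.to_datetime(df["timestamp"])
            streams[path.stem] = df
        return cls(participants=participants, streams=streams, place_tags=place_tags)


def _sentiment_to_pneg(target: float) -> float:
    # packaged lexicon has mean |score| ~ 0.65 in each pool
    return float(np.clip((1.0 - target / 0.65) / 2.0, 0.02, 0.98))


def _draw_tokens(rng, n: int, p_neg: float, pos_pool, neg_pool) -> list[str]:
    toks = []
    for _ in range(n):
        u = rng.random()
        if u < 0.5:
            toks.append(_FILLER_TOKENS[int(rng.integers(len(_FILLER_TOKENS)))])
        elif rng.random() < p_neg:
            toks.append(neg_pool[int(rng.integers(len(neg_pool)))])
        else:
            toks.append(pos_pool[int(rng.integers(len(pos_pool)))])
    return toks


@functools.lru_cache(maxsize=1)
def _lexicon_pools() -> tuple[tuple[str, ...], tuple[str, ...]]:
    lex = load_lexicon()
    pos = tuple(t for t, s in lex.items() if s > 0)
    neg = tuple(t for t, s in lex.items() if s < 0)
    return pos, neg


def generate_participant(
    participant_id: str,
    arm: str,
    cfg: CohortConfig,
    seed_seq: np.random.SeedSequence,
) -> ParticipantData:
    """Realize every stream for one participant (deterministic in seed)."""
    rng = np.random.default_rng(seed_seq)
    n_weeks, n_days = cfg.n_weeks, cfg.n_days
    start = pd.Timestamp(cfg.start_date)
    mu_d, mu_n = calibrate_arm_means(round(_severity_sd(cfg), 9))
    sev = simulate_severity(rng, mu_d if arm == "depressed" else mu_n, cfg)
    mix_mean, mix_sd = severity_mixture_stats(cfg, mu_d, mu_n)
    sev_z = (sev - mix_mean) / mix_sd
    eff = cfg.effect_sizes
    targets = weekly_targets(rng, sev_z, eff)

    miss = cfg.missingness
    absent = {s: bool(rng.random() < p) for s, p in sorted(miss.p_sensor_absent.items())}
    dropout = rng.random(n_days) < miss.p_day_dropout

    week_of_day = np.arange(n_days) // 7
    minute_ts = start + pd.to_timedelta(np.arange(n_days * 1440), unit="m")
    day_of_minute = np.repeat(np.arange(n_days), 1440)

    # --- location -----------------------------------------------------------
    anchors = _make_anchors(rng)
    g_out = 4.0 * eff.get("unique_location_clusters", 0.0)
    g_skip = 4.0 * eff.get("time_spent_at_home", 0.0)
    g_hosp = 4.0 * eff.get("time_spent_at_hospital", 0.0)
    hosp_week = rng.random(n_weeks) < np.clip(0.25 * np.exp(g_hosp * sev_z), 0.0, 1.0)
    hosp_day = np.full(n_days, False)
    for w in np.flatnonzero(hosp_week):
        hosp_day[w * 7 + int(rng.integers(7))] = True

    lat_all = np.empty(n_days * 1440)
    lon_all = np.empty(n_days * 1440)
    dest_pool = np.arange(2, len(anchors))
    for d in range(n_days):
        w = week_of_day[d]
        weekday = (start + pd.Timedelta(days=int(d))).dayofweek < 5
        work_today = weekday and rng.random() > expit(-2.6 + g_skip * sev_z[w])
        lam = 1.1 * math.exp(g_out * sev_z[w])
        state, frac, t_from, t_to, t_seg = _schedule_day(rng, weekday, work_today, lam, dest_pool, bool(hosp_day[d]))
        lat, lon = _positions(rng, anchors, state, frac, t_from, t_to, t_seg, cfg.jitter_m)
        lat_all[d * 1440 : (d + 1) * 1440] = lat
        lon_all[d * 1440 : (d + 1) * 1440] = lon

    # --- minutely level streams ---------------------------------------------
    rep = np.repeat(targets.to_numpy(), 1440 * 7, axis=0)[: n_days * 1440]
    col = {name: i for i, name in enumerate(targets.columns)}
    n_min = n_days * 1440
    audio = np.clip(rep[:, col["ambient_audio_level"]] + rng.normal(0, 8, n_min), 0, None)
    light = np.clip(rep[:, col["ambient_light_level"]] + rng.normal(0, 60, n_min), 0, None)
    pressure = rng.normal(1013.0, 2.0, n_min)
    proximity = (rng.random(n_min) < 0.35).astype(int)
    act_target = np.repeat(
        np.clip(targets["physically_active_minutes"].to_numpy()[week_of_day] + rng.normal(0, 6, n_days), 0, 600),
        1440,
    )
    activity = (rng.random(n_min) < act_target / 1440.0).astype(int)

    # battery: daily mean around weekly target, one nightly charging block
    batt_day = np.clip(
        targets["battery_percentage"].to_numpy()[week_of_day] + rng.normal(0, 3, n_days), 5, 98
    )
    batt = np.clip(np.repeat(batt_day, 1440) + rng.normal(0, 6, n_min), 1, 100)
    chg_min = np.clip(
        targets["charging_minutes"].to_numpy()[week_of_day] + rng.normal(0, 15, n_days), 5, 600
    ).astype(int)
    charging = np.zeros(n_min, dtype=int)
    for d in range(n_days):
        s = int(rng.integers(0, 1440 - chg_min[d]))
        charging[d * 1440 + s : d * 1440 + s + chg_min[d]] = 1

    def minutely_mask(stream: str) -> np.ndarray:
        keep = ~dropout[day_of_minute]
        if miss.p_minute_gap > 0:
            keep &= rng.random(n_min) >= miss.p_minute_gap
        else:
            # burn no draws when gaps are disabled, keeping rngs comparable
            pass
        if absent.get(stream, False):
            keep &= False
        return keep

    streams: dict[str, pd.DataFrame] = {}

    def add_minutely(name: str, values: np.ndarray) -> None:
        keep = minutely_mask(name)
        streams[name] = pd.DataFrame(
            {
                "participant_id": participant_id,
                "timestamp": minute_ts[keep],
                "value": values[keep],
            }
        )

    add_minutely("ping", np.ones(n_min, dtype=int))
    add_minutely("ambient_audio", np.round(audio, 3))
    add_minutely("ambient_light", np.round(light, 3))
    add_minutely("activity", activity)
    add_minutely("pressure", np.round(pressure, 3))
    add_minutely("proximity", proximity)

    keep_loc = minutely_mask("location")
    streams["location"] = pd.DataFrame(
        {
            "participant_id": participant_id,
            "timestamp": minute_ts[keep_loc],
            "lat": np.round(lat_all[keep_loc], 7),
            "lon": np.round(lon_all[keep_loc], 7),
        }
    )

    keep_batt = minutely_mask("battery")
    streams["battery"] = pd.DataFrame(
        {
            "participant_id": participant_id,
            "timestamp": minute_ts[keep_batt],
            "percent": np.round(batt[keep_batt], 2),
            "charging": charging[keep_batt],
        }
    )

    # --- screen sessions -----------------------------------------------------
    scr_rows: list[tuple] = []
    scr_target = np.clip(
        targets["phone_screen_on_minutes"].to_numpy()[week_of_day] + rng.normal(0, 25, n_days), 5, 1000
    )
    for d in range(n_days):
        if dropout[d] or absent.get("screen", False):
            continue
        n_sessions = max(1, int(rng.poisson(18)))
        starts = np.sort(rng.choice(1438, size=min(n_sessions, 200), replace=False))
        gaps = np.diff(np.append(starts, 1439))
        weights = rng.exponential(1.0, size=starts.size)
        durs = np.maximum(1, np.minimum(gaps, np.round(scr_target[d] * weights / weights.sum()).astype(int)))
        base_ts = start + pd.Timedelta(days=int(d))
        for s, du in zip(starts, durs):
            scr_rows.append((participant_id, base_ts + pd.Timedelta(minutes=int(s)), "on"))
            scr_rows.append((participant_id, base_ts + pd.Timedelta(minutes=int(s + du)), "off"))
    streams["screen"] = pd.DataFrame(scr_rows, columns=["participant_id", "timestamp", "state"])

    # --- volume settings (one reading per channel per day) -------------------
    vol_rows = []
    for channel, feat in (
        ("system", "audio_system_volume"),
        ("ring", "ring_volume"),
        ("notification", "audio_notification_volume"),
    ):
        levels = np.clip(targets[feat].to_numpy()[week_of_day] + rng.normal(0, 0.04, n_days), 0, 1)
        for d in range(n_days):
            if dropout[d] or absent.get("volume", False):
                continue
            vol_rows.append(
                (participant_id, (start + pd.Timedelta(days=int(d))).date().isoformat(), channel, round(levels[d], 4))
            )
    streams["volume"] = pd.DataFrame(vol_rows, columns=["participant_id", "date", "channel", "level"])

    # --- wifi scans (hourly) --------------------------------------------------
    wifi_rows = []
    if not absent.get("wifi", False):
        pool = np.arange(40)
        nw_t = targets["n_wifi_networks"].to_numpy()[week_of_day]
        nb_t = targets["nearby_wifi_count"].to_numpy()[week_of_day]
        for d in range(n_days):
            if dropout[d]:
                continue
            n_distinct = max(1, int(round(nw_t[d] + rng.normal(0, 1))))
            todays = rng.choice(pool, size=min(n_distinct, pool.size), replace=False)
            base_ts = start + pd.Timedelta(days=int(d))
            for h in range(24):
                ssid = int(todays[h % todays.size])
                wifi_rows.append(
                    (
                        participant_id,
                        base_ts + pd.Timedelta(hours=h),
                        f"net{ssid:03d}",
                        int(rng.poisson(max(nb_t[d], 0.1))),
                    )
                )
    streams["wifi"] = pd.DataFrame(wifi_rows, columns=["participant_id", "timestamp", "ssid", "n_nearby"])

    # --- app usage -------------------------------------------------------------
    app_rows = []
    cat_apps = {
        "social": ("chatterly", "snapgram", "friendfeed"),
        "wellness": ("mindfulpath", "calmspace", "stepstracker"),
        "communication": ("textly", "mailhub", "callhub"),
    }
    if not absent.get("app_usage", False):
        for d in range(n_days):
            if dropout[d] or rng.random() < 0.07:  # residual daily logging gaps
                continue
            date = (start + pd.Timedelta(days=int(d))).date().isoformat()
            for cat, apps in cat_apps.items():
                feat = f"{cat}_apps_usage"
                total = max(0.0, targets[feat].to_numpy()[week_of_day[d]] + rng.normal(0, 0.25 * FEATURE_GEN[feat][0] + 1))
                w = rng.dirichlet(np.ones(len(apps)))
                for app, share in zip(apps, w):
                    mins = round(float(total * share), 2)
                    if mins > 0.25:
                        app_rows.append((participant_id, date, app, mins))
            app_rows.append((participant_id, date, "newsreader", round(float(rng.exponential(8.0)), 2)))
    streams["app_usage"] = pd.DataFrame(app_rows, columns=["participant_id", "date", "app", "minutes"])

    # --- sleep self-report ------------------------------------------------------
    sleep_rows = []
    if not absent.get("sleep_report", False):
        hours_t = targets["reported_sleep_duration"].to_numpy()[week_of_day]
        for d in range(n_days):
            if rng.random() < miss.p_sleep_missing:
                continue
            sleep_rows.append(
                (
                    participant_id,
                    (start + pd.Timedelta(days=int(d))).date().isoformat(),
                    round(float(np.clip(hours_t[d] + rng.normal(0, 0.7), 0.5, 16.0)), 2),
                )
            )
    streams["sleep_report"] = pd.DataFrame(sleep_rows, columns=["participant_id", "date", "hours"])

    # --- calls -------------------------------------------------------------------
    call_rows = []
    if not absent.get("calls", False):
        lam_call = np.maximum(targets["phone_call_count"].to_numpy()[week_of_day], 0.05)
        ring_t = targets["ring_until_missed_minutes"].to_numpy()[week_of_day]
        in_t = targets["incoming_phone_call_duration"].to_numpy()[week_of_day]
        out_t = targets["outgoing_phone_call_duration"].to_numpy()[week_of_day]
        for d in range(n_days):
            if dropout[d]:
                continue
            n_calls = int(rng.poisson(lam_call[d]))
            base_ts = start + pd.Timedelta(days=int(d))
            exp_answered_in = max(lam_call[d] * 0.55 * 0.7, 0.2)
            exp_missed_in = max(lam_call[d] * 0.55 * 0.3, 0.1)
            exp_out = max(lam_call[d] * 0.45, 0.2)
            for _ in range(n_calls):
                minute = int(rng.integers(8 * 60, 22 * 60))
                ts = base_ts + pd.Timedelta(minutes=minute)
                incoming = rng.random() < 0.55
                if incoming and rng.random() < 0.3:
                    ring = float(np.clip(rng.normal(ring_t[d] * 60.0 / exp_missed_in, 15), 5, 600))
                    call_rows.append((participant_id, ts, "incoming", "missed", round(ring, 1), 0.0))
                else:
                    direction = "incoming" if incoming else "outgoing"
                    mean_dur = (in_t[d] / exp_answered_in) if incoming else (out_t[d] / exp_out)
                    dur = float(np.clip(rng.normal(mean_dur, max(mean_dur * 0.4, 10)), 5, 7200))
                    ring = float(np.clip(rng.normal(12, 4), 2, 60))
                    call_rows.append((participant_id, ts, direction, "answered", round(ring, 1), round(dur, 1)))
    streams["calls"] = pd.DataFrame(
        call_rows, columns=["participant_id", "timestamp", "direction", "outcome", "ring_s", "duration_s"]
    )

    # --- texts --------------------------------------------------------------------
    pos_pool, neg_pool = _lexicon_pools()
    text_rows = []
    if not absent.get("texts", False):
        cnt_t = np.maximum(targets["text_message_count"].to_numpy()[week_of_day], 0.05)
        body_t = np.maximum(targets["text_message_body_size"].to_numpy()[week_of_day], 10.0)
        emo_t = np.maximum(targets["text_message_emoji_count"].to_numpy()[week_of_day], 0.0)
        sent_t = targets["outgoing_text_sentiment"].to_numpy()[week_of_day]
        for d in range(n_days):
            if dropout[d]:
                continue
            base_ts = start + pd.Timedelta(days=int(d))
            n_out = int(rng.poisson(cnt_t[d]))
            p_neg = _sentiment_to_pneg(sent_t[d])
            tok_per_msg = float(np.clip(body_t[d] / (5.8 * max(n_out, 1)), 1, 80))
            emo_per_msg = emo_t[d] / max(n_out, 1)
            for _ in range(n_out):
                minute = int(rng.integers(7 * 60, 23 * 60))
                toks = _draw_tokens(rng, max(1, int(rng.poisson(tok_per_msg))), p_neg, pos_pool, neg_pool)
                emojis = "".join(
                    _EMOJI_POOL[int(rng.integers(len(_EMOJI_POOL)))] for _ in range(int(rng.poisson(emo_per_msg)))
                )
                body = " ".join(toks) + emojis
                text_rows.append((participant_id, base_ts + pd.Timedelta(minutes=minute), "outgoing", body))
            for _ in range(int(rng.poisson(2.0))):
                minute = int(rng.integers(7 * 60, 23 * 60))
                toks = _draw_tokens(rng, max(1, int(rng.poisson(6.0))), 0.3, pos_pool, neg_pool)
                text_rows.append((participant_id, base_ts + pd.Timedelta(minutes=minute), "incoming", " ".join(toks)))
    streams["texts"] = pd.DataFrame(text_rows, columns=["participant_id", "timestamp", "direction", "body"])

    # --- weekly voice diary ----------------------------------------------------
    diary_rows = []
    for w in range(n_weeks):
        if rng.random() < miss.p_diary_missing:
            continue
        dur = float(np.clip(targets["voice_diary_duration"].iloc[w] + rng.normal(0, 8), 15, 900))
        wpm = float(np.clip(targets["voice_diary_words_per_minute"].iloc[w] + rng.normal(0, 4), 20, 240))
        n_tok = max(3, int(round(wpm * dur / 60.0)))
        p_neg = _sentiment_to_pneg(float(targets["voice_diary_sentiment"].iloc[w]))
        toks = _draw_tokens(rng, n_tok, p_neg, pos_pool, neg_pool)
        n_pause = 1 + int(rng.poisson(5))
        pauses = np.clip(rng.normal(targets["voice_diary_pauses_duration"].iloc[w], 0.3, n_pause), 0.05, None)
        if pauses.sum() > 0.5 * dur:  # pauses cannot exceed the recording
            pauses = pauses * (0.5 * dur / pauses.sum())
        diary_rows.append(
            (
                participant_id,
                w,
                " ".join(toks),
                round(dur, 1),
                ";".join(f"{p:.2f}" for p in pauses),
            )
        )
    streams["diary"] = pd.DataFrame(
        diary_rows, columns=["participant_id", "week_index", "transcript", "duration_s", "pauses_s"]
    )

    # --- weekly PHQ-9 ------------------------------------------------------------
    phq_rows = []
    for w in range(n_weeks):
        items = severity_to_phq9(sev[w], rng)
        if rng.random() < miss.p_phq9_missing:
            continue
        phq_rows.append((participant_id, w, *items.tolist(), int(items.sum())))
    streams["phq9"] = pd.DataFrame(
        phq_rows,
        columns=["participant_id", "week_index"] + [f"item{i}" for i in range(1, 10)] + ["phq9_sum"],
    )

    place_tags = pd.DataFrame(
        {
            "participant_id": participant_id,
            "anchor_id": np.arange(len(anchors)),
            "lat": np.round(anchors[:, 0], 7),
            "lon": np.round(anchors[:, 1], 7),
            "tags": list(ANCHOR_TAGS[: len(anchors)]),
        }
    )
    return ParticipantData(
        participant_id=participant_id,
        arm=arm,
        severity=sev,
        streams=streams,
        place_tags=place_tags,
    )


def _roster(cfg: CohortConfig) -> list[tuple[str, str]]:
    n_dep = cfg.n_depressed
    return [
        (f"P{i:04d}", "depressed" if i < n_dep else "control")
        for i in range(cfg.n_participants)
    ]


def iter_participants(cfg: CohortConfig) -> Iterator[ParticipantData]:
    """Stream participants one at a time (memory-light path)."""
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.n_participants)
    for (pid, arm), seq in zip(_roster(cfg), seqs):
        yield generate_participant(pid, arm, cfg, seq)


def generate_cohort(cfg: CohortConfig) -> StudyData:
    """Materialize the full synthetic study dataset.

    Deterministic: identical (config, seed) pairs produce byte-identical
    serialized output.
    """
    parts = list(iter_participants(cfg))
    participants = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in parts],
            "arm": [p.arm for p in parts],
            "enrollment_date": cfg.start_date,
        }
    )
    stream_names = sorted({name for p in parts for name in p.streams})
    streams = {}
    for name in stream_names:
        frames = [p.streams[name] for p in parts if name in p.streams]
        nonempty = [f for f in frames if len(f)]
        streams[name] = (
            pd.concat(nonempty, ignore_index=True) if nonempty else frames[0].copy()
        )
    place_tags = pd.concat([p.place_tags for p in parts], ignore_index=True)
    return StudyData(participants=participants, streams=streams, place_tags=place_tags)


# ---------------------------------------------------------------------------
# Weekly-marginal fast path

def simulate_feature_matrix(
    cfg: CohortConfig, apply_missingness: bool = True, include_latent: bool = False
) -> pd.DataFrame:
    """Draw the 34 weekly features directly from the weekly target model.

    Skips the minutely realization: each participant-week's features come
    from the same ``base + scale * (effect * severity_z + noise)`` model
    that parametrizes the full generator, plus small measurement noise.
    Suited to replicate-heavy statistical checks (null calibration, sign
    recovery) where minutely fidelity adds nothing but cost.
    """
    rng = np.random.default_rng(cfg.seed)
    mu_d, mu_n = calibrate_arm_means(round(_severity_sd(cfg), 9))
    mix_mean, mix_sd = severity_mixture_stats(cfg, mu_d, mu_n)
    miss = cfg.missingness
    rows = []
    for pid, arm in _roster(cfg):
        sev = simulate_severity(rng, mu_d if arm == "depressed" else mu_n, cfg)
        sev_z = (sev - mix_mean) / mix_sd
        targets = weekly_targets(rng, sev_z, cfg.effect_sizes)
        app_absent = apply_missingness and rng.random() < miss.p_sensor_absent.get("app_usage", 0.0)
        sleep_absent = apply_missingness and rng.random() < miss.p_sensor_absent.get("sleep_report", 0.0)
        for w in range(cfg.n_weeks):
            row: dict[str, object] = {"participant_id": pid, "week_index": w, "n_sufficient_days": 7}
            if include_latent:
                row["latent_severity"] = float(sev[w])
            for name in FEATURE_NAMES:
                base, scale, lo, hi = FEATURE_GEN[name]
                if name in INDICATOR_FEATURES:
                    continue
                val = targets[name].iloc[w] + rng.normal(0.0, 0.25 * scale if scale else 0.0)
                row[name] = float(np.clip(val, lo, hi))
            row["app_usage_missing"] = 1.0 if app_absent else float(rng.binomial(7, 0.07)) / 7.0
            row["reported_sleep_duration_missing"] = (
                1.0 if sleep_absent else float(rng.binomial(7, 0.10)) / 7.0
            )
            if app_absent:
                for cat in ("social", "wellness", "communication"):
                    row[f"{cat}_apps_usage"] = np.nan
            if sleep_absent:
                row["reported_sleep_duration"] = np.nan
            if apply_missingness:
                for name in FEATURE_NAMES:
                    if name in INDICATOR_FEATURES or name == "reported_sleep_duration":
                        continue
                    if rng.random() < 0.04:
                        row[name] = np.nan
            items = severity_to_phq9(sev[w], rng)
            if apply_missingness and rng.random() < miss.p_phq9_missing:
                row["phq9_sum"] = np.nan
            else:
                row["phq9_sum"] = float(items.sum())
            rows.append(row)
    df = pd.DataFrame(rows)
    df["depressed_week"] = np.where(df["phq9_sum"].isna(), np.nan, (df["phq9_sum"] >= 10).astype(float))
    cols = ["participant_id", "week_index", "n_sufficient_days"] + list(FEATURE_NAMES) + ["phq9_sum", "depressed_week"]
    if include_latent:
        cols = cols[:3] + ["latent_severity"] + cols[3:]
    return df[cols]
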