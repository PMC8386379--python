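"""GPS location clustering and the mobility feature family.

Minutely latitude/longitude traces are clustered with DBSCAN under
haversine distance, once per participant over the whole study.  Clusters
are then labeled with time-bounded heuristics: *home* is the single
cluster holding the most minutes between 11 PM and 4 AM across the study;
*work* is any non-home cluster holding at least 15% of the participant's
clustered 10 AM-3 PM minutes; *commute* is transit between the two.
Weekly features derived from the assignment: number of unique clusters
visited, Shannon entropy of the cluster time distribution (nats), spatial
variance (degrees^2), and time budgets at home and at hospital-tagged
places.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

__all__ = [
    "EARTH_RADIUS_M",
    "cluster_locations",
    "cluster_centroids",
    "label_home",
    "work_shares",
    "label_work",
    "commute_minutes",
    "location_entropy",
    "location_variance",
    "cluster_place_tags",
    "daily_location_budget",
]

EARTH_RADIUS_M = 6_371_000.0
M_PER_DEG_LAT = 111_320.0

NIGHT_HOURS = frozenset({23, 0, 1, 2, 3})  # 11 PM-4 AM, spanning midnight
WORK_HOURS = frozenset({10, 11, 12, 13, 14})  # 10 AM-3 PM


def cluster_locations(
    lat: Sequence[float],
    lon: Sequence[float],
    eps_m: float = 30.0,
    min_samples: int = 5,
    grid_m: float | None = None,
) -> np.ndarray:
    """Density-cluster GPS points; returns one label per point (-1 = noise).

    With ``grid_m`` set, points are first binned to a spatial grid of that
    pitch and DBSCAN runs on the occupied cells with occupancy weights;
    each raw point inherits its cell's label.  This is exact up to the
    sub-grid displacement and keeps long dense traces (tens of thousands
    of co-located minutes) tractable.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size == 0:
        raise ValueError("cluster_locations requires at least one point")
    if eps_m <= 0 or min_samples < 1:
        raise ValueError("eps_m must be > 0 and min_samples >= 1")

    if grid_m is None:
        pts = np.radians(np.column_stack([lat, lon]))
        model = DBSCAN(
            eps=eps_m / EARTH_RADIUS_M,
            min_samples=min_samples,
            metric="haversine",
            algorithm="ball_tree",
        ).fit(pts)
        return model.labels_.astype(int)

    lat0 = float(np.mean(lat))
    m_per_deg_lon = M_PER_DEG_LAT * max(np.cos(np.radians(lat0)), 1e-6)
    ix = np.floor(lat * M_PER_DEG_LAT / grid_m).astype(np.int64)
    iy = np.floor(lon * m_per_deg_lon / grid_m).astype(np.int64)
    # single integer key per cell (offsets keep negatives collision-free)
    key = (ix + 2**31).astype(np.uint64) * np.uint64(2**32) + (iy + 2**31).astype(np.uint64)
    _, inverse, counts = np.unique(key, return_inverse=True, return_counts=True)
    # representative point per cell = mean of member coordinates
    rep_lat = np.bincount(inverse, weights=lat) / counts
    rep_lon = np.bincount(inverse, weights=lon) / counts
    pts = np.radians(np.column_stack([rep_lat, rep_lon]))
    model = DBSCAN(
        eps=eps_m / EARTH_RADIUS_M,
        min_samples=min_samples,
        metric="haversine",
        algorithm="ball_tree",
    ).fit(pts, sample_weight=counts)
    return model.labels_[inverse].astype(int)


def cluster_centroids(lat: np.ndarray, lon: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster weighted mean coordinates and member counts."""
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    labels = np.asarray(labels)
    keep = labels >= 0
    if not keep.any():
        return pd.DataFrame(columns=["cluster", "lat", "lon", "n"]).set_index("cluster")
    df = pd.DataFrame({"cluster": labels[keep], "lat": lat[keep], "lon": lon[keep]})
    out = df.groupby("cluster").agg(lat=("lat", "mean"), lon=("lon", "mean"), n=("lat", "size"))
    return out


def _night_mask(timestamps: pd.DatetimeIndex) -> np.ndarray:
    hours = timestamps.hour
    return np.isin(hours, list(NIGHT_HOURS))


def label_home(labels: np.ndarray, timestamps) -> int | None:
    """The single cluster with maximal 11 PM-4 AM minutes, or None.

    Evaluated over the full study so home is one fixed place; minutes from
    23:00-23:59 belong to the following night's window.  Ties break to the
    smaller cluster id for determinism.
    """
    labels = np.asarray(labels)
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps))
    mask = _night_mask(ts) & (labels >= 0)
    if not mask.any():
        return None
    counts = pd.Series(labels[mask]).value_counts()
    top = counts[counts == counts.max()]
    return int(min(top.index))


def work_shares(labels: np.ndarray, timestamps) -> pd.Series:
    """Fraction of clustered 10 AM-3 PM minutes per cluster."""
    labels = np.asarray(labels)
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps))
    mask = np.isin(ts.hour, list(WORK_HOURS)) & (labels >= 0)
    if not mask.any():
        return pd.Series(dtype=float)
    counts = pd.Series(labels[mask]).value_counts()
    return counts / counts.sum()


def label_work(
    labels: np.ndarray,
    timestamps,
    home_id: int | None,
    threshold: float = 0.15,
) -> set[int]:
    """All non-home clusters holding >= ``threshold`` of the 10 AM-3 PM
    clustered minutes in the scoring window (can be several places)."""
    shares = work_shares(labels, timestamps)
    return {int(c) for c, s in shares.items() if s >= threshold and c != home_id}


def commute_minutes(
    labels: Sequence[int],
    home_id: int | None,
    work_ids: Iterable[int],
) -> int:
    """Minutes in transit directly between home and work.

    ``labels`` is the chronological per-minute cluster assignment.  A
    commute segment is a maximal run of unclustered minutes whose flanking
    dwells are (home, work) or (work, home); a dwell in any other cluster
    in between breaks the segment.
    """
    work_ids = set(int(w) for w in work_ids)
    if home_id is None or not work_ids:
        return 0
    total = 0
    prev_cluster: int | None = None
    gap = 0
    for lab in np.asarray(labels):
        lab = int(lab)
        if lab < 0:
            gap += 1
            continue
        if prev_cluster is not None and lab != prev_cluster:
            a, b = prev_cluster, lab
            if (a == home_id and b in work_ids) or (a in work_ids and b == home_id):
                total += gap
        prev_cluster = lab
        gap = 0
    return int(total)


def location_entropy(minutes_per_cluster: Sequence[float]) -> float:
    """Shannon entropy (nats) of the weekly cluster-minute distribution."""
    m = np.asarray(list(minutes_per_cluster), dtype=float)
    if m.size == 0 or (m < 0).any() or m.sum() <= 0:
        raise ValueError("entropy needs nonnegative minutes with a positive total")
    p = m[m > 0] / m.sum()
    return float(-(p * np.log(p)).sum())


def location_variance(lat: Sequence[float], lon: Sequence[float]) -> float:
    """var(latitude) + var(longitude), population form, in degrees^2."""
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    if lat.size < 2:
        return float("nan")
    return float(np.var(lat) + np.var(lon))


def cluster_place_tags(
    centroids: pd.DataFrame,
    place_tags: pd.DataFrame,
    radius_m: float = 100.0,
) -> dict[int, set[str]]:
    """Semantic tags per cluster from a synthetic place-tag table.

    ``place_tags`` carries one row per tagged anchor (lat, lon, tags with
    ``;`` separators).  A cluster collects the tags of every anchor within
    ``radius_m`` of its centroid, so one place can carry several types.
    """
    tags: dict[int, set[str]] = {}
    if centroids.empty or place_tags.empty:
        return tags
    clat = np.radians(centroids["lat"].to_numpy())
    clon = np.radians(centroids["lon"].to_numpy())
    alat = np.radians(place_tags["lat"].to_numpy())
    alon = np.radians(place_tags["lon"].to_numpy())
    for i, cluster in enumerate(centroids.index):
        dlat = alat - clat[i]
        dlon = alon - clon[i]
        a = np.sin(dlat / 2) ** 2 + np.cos(clat[i]) * np.cos(alat) * np.sin(dlon / 2) ** 2
        dist = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
        near = np.flatnonzero(dist <= radius_m)
        if near.size:
            tagset: set[str] = set()
            for j in near:
                tagset.update(str(place_tags["tags"].iloc[j]).split(";"))
            tags[int(cluster)] = tagset
    return tags


def daily_location_budget(
    timestamps,
    labels: Sequence[int],
    day_index: Sequence[int],
    home_id: int | None,
    work_ids: Iterable[int],
    tagged: dict[int, set[str]] | None = None,
) -> pd.DataFrame:
    """Stacked daily minutes by semantic category (for budget bar charts).

    Categories: home, work, hospital (tagged "hospital or doctor's
    office"), exercise (tagged "place to exercise"), other cluster,
    commute (home<->work transit) and unclustered.
    """
    labels = np.asarray(labels)
    day_index = np.asarray(day_index)
    work_ids = set(int(w) for w in work_ids)
    tagged = tagged or {}
    hospital = {c for c, t in tagged.items() if "hospital or doctor's office" in t}
    exercise = {c for c, t in tagged.items() if "place to exercise" in t}

    cat = np.full(labels.shape, "unclustered", dtype=object)
    for c in np.unique(labels[labels >= 0]):
        name = "other cluster"
        if home_id is not None and c == home_id:
            name = "home"
        elif c in work_ids:
            name = "work"
        elif c in hospital:
            name = "hospital"
        elif c in exercise:
            name = "exercise"
        cat[labels == c] = name

    # re-mark unclustered minutes that form direct home<->work transit
    order = np.argsort(np.asarray(pd.DatetimeIndex(pd.to_datetime(timestamps)).asi8), kind="stable")
    lab_sorted = labels[order]
    commute_sorted = np.zeros(lab_sorted.shape, dtype=bool)
    prev_cluster = None
    gap_idx: list[int] = []
    for i, lab in enumerate(lab_sorted):
        lab = int(lab)
        if lab < 0:
            gap_idx.append(i)
            continue
        if prev_cluster is not None and lab != prev_cluster:
            a, b = prev_cluster, lab
            if home_id is not None and (
                (a == home_id and b in work_ids) or (a in work_ids and b == home_id)
            ):
                commute_sorted[gap_idx] = True
        prev_cluster = lab
        gap_idx = []
    commute = np.zeros_like(commute_sorted)
    commute[order] = commute_sorted
    cat[commute] = "commute"

    df = pd.DataFrame({"day": day_index, "category": cat})
    out = df.groupby(["day", "category"]).size().unstack(fill_value=0)
    return out
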