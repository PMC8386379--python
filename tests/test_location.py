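"""GPS clustering, place labeling and mobility features."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenoweek.location import (
    cluster_centroids,
    cluster_locations,
    commute_minutes,
    label_home,
    label_work,
    location_entropy,
    location_variance,
)

LAT0, LON0 = 40.0, -75.0
M_PER_DEG = 111_320.0


def jittered(rng, lat, lon, n, sigma_m=5.0):
    return (
        lat + rng.normal(0, sigma_m / M_PER_DEG, n),
        lon + rng.normal(0, sigma_m / (M_PER_DEG * math.cos(math.radians(lat))), n),
    )


class TestClusterLocations:
    def test_single_dense_blob(self):
        rng = np.random.default_rng(0)
        lat, lon = jittered(rng, LAT0, LON0, 100)
        labels = cluster_locations(lat, lon, eps_m=30, min_samples=5)
        assert set(labels) == {0}

    def test_two_blobs_10km_apart(self):
        rng = np.random.default_rng(1)
        la1, lo1 = jittered(rng, LAT0, LON0, 50)
        la2, lo2 = jittered(rng, LAT0 + 10000 / M_PER_DEG, LON0, 50)
        labels = cluster_locations(np.r_[la1, la2], np.r_[lo1, lo2], eps_m=30, min_samples=5)
        assert len(set(labels)) == 2 and -1 not in set(labels)

    def test_isolated_points_are_noise(self):
        # 4 points, each km apart: no core point can reach min_samples=5
        lat = LAT0 + np.arange(4) * 1000 / M_PER_DEG
        lon = np.full(4, LON0)
        labels = cluster_locations(lat, lon, eps_m=30, min_samples=5)
        assert (labels == -1).all()

    def test_point_order_invariant_up_to_relabeling(self):
        rng = np.random.default_rng(2)
        la1, lo1 = jittered(rng, LAT0, LON0, 40)
        la2, lo2 = jittered(rng, LAT0, LON0 + 0.05, 40)
        lat, lon = np.r_[la1, la2], np.r_[lo1, lo2]
        perm = rng.permutation(lat.size)
        a = cluster_locations(lat, lon, eps_m=30, min_samples=5)
        b = np.empty_like(a)
        b_perm = cluster_locations(lat[perm], lon[perm], eps_m=30, min_samples=5)
        b[perm] = b_perm
        # identical partitions: same co-membership structure
        for i in range(0, lat.size, 7):
            assert ((a == a[i]) == (b == b[i])).all()

    def test_grid_mode_matches_exact_on_separated_blobs(self):
        rng = np.random.default_rng(3)
        la1, lo1 = jittered(rng, LAT0, LON0, 60)
        la2, lo2 = jittered(rng, LAT0 + 0.05, LON0, 60)
        lat, lon = np.r_[la1, la2], np.r_[lo1, lo2]
        exact = cluster_locations(lat, lon, eps_m=30, min_samples=5)
        binned = cluster_locations(lat, lon, eps_m=30, min_samples=5, grid_m=3.0)
        for i in range(0, lat.size, 11):
            assert ((exact == exact[i]) == (binned == binned[i])).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_locations([], [])

    def test_weighted_centroid_is_member_mean(self):
        rng = np.random.default_rng(4)
        lat, lon = jittered(rng, LAT0, LON0, 30)
        labels = cluster_locations(lat, lon, eps_m=30, min_samples=5)
        cent = cluster_centroids(lat, lon, labels)
        assert cent.loc[0, "lat"] == pytest.approx(lat[labels == 0].mean())
        assert cent.loc[0, "n"] == int((labels == 0).sum())


def night_and_day_stamps(n_night_a, n_night_b, n_day):
    """Timestamps: night minutes split between two clusters, day minutes in A."""
    stamps, labels = [], []
    t0 = pd.Timestamp("2018-01-01 23:00")
    for i in range(n_night_a):
        stamps.append(t0 + pd.Timedelta(minutes=i % 300))
        labels.append(0)
    for i in range(n_night_b):
        stamps.append(pd.Timestamp("2018-01-02 00:30") + pd.Timedelta(minutes=i % 180))
        labels.append(1)
    for i in range(n_day):
        stamps.append(pd.Timestamp("2018-01-02 12:00") + pd.Timedelta(minutes=i % 120))
        labels.append(0)
    return np.asarray(labels), pd.DatetimeIndex(stamps)


class TestHomeWorkLabels:
    def test_all_night_points_in_one_cluster(self):
        labels, ts = night_and_day_stamps(100, 0, 50)
        assert label_home(labels, ts) == 0

    def test_no_night_window_points_gives_none(self):
        ts = pd.date_range("2018-01-01 10:00", periods=60, freq="min")
        assert label_home(np.zeros(60, dtype=int), ts) is None

    def test_max_night_minutes_wins(self):
        labels, ts = night_and_day_stamps(300, 200, 0)
        assert label_home(labels, ts) == 0
        labels, ts = night_and_day_stamps(150, 200, 0)
        assert label_home(labels, ts) == 1

    def test_2300_to_midnight_counts_toward_night(self):
        ts = pd.date_range("2018-01-01 23:00", periods=59, freq="min")
        assert label_home(np.zeros(59, dtype=int), ts) == 0

    def work_window(self, shares):
        """Labels/timestamps with given per-cluster shares of 10 AM-3 PM."""
        stamps, labels = [], []
        t0 = pd.Timestamp("2018-01-01 10:00")
        minute = 0
        for cluster, n in shares.items():
            for _ in range(n):
                stamps.append(t0 + pd.Timedelta(minutes=minute % 300))
                labels.append(cluster)
                minute += 1
        return np.asarray(labels), pd.DatetimeIndex(stamps)

    def test_just_below_threshold_excluded(self):
        labels, ts = self.work_window({1: 149, 2: 851})  # 14.9% vs 85.1%
        assert label_work(labels, ts, home_id=None) == {2}

    def test_home_cluster_excluded_despite_share(self):
        labels, ts = self.work_window({0: 180, 1: 120})  # home holds 60%
        assert label_work(labels, ts, home_id=0) == {1}

    def test_multiple_work_clusters_allowed(self):
        labels, ts = self.work_window({1: 60, 2: 90, 3: 150})  # 20%, 30%, 50%
        assert label_work(labels, ts, home_id=None) == {1, 2, 3}
        labels, ts = self.work_window({1: 20, 2: 30, 3: 50})
        assert label_work(labels, ts, home_id=None) == {1, 2, 3}


class TestCommute:
    def test_single_transit(self):
        labels = [0] * 30 + [-1] * 20 + [1] * 60
        assert commute_minutes(labels, home_id=0, work_ids={1}) == 20

    def test_no_work_cluster_gives_zero(self):
        labels = [0] * 30 + [-1] * 20 + [1] * 60
        assert commute_minutes(labels, home_id=0, work_ids=set()) == 0

    def test_round_trip_sums_both_legs(self):
        labels = [0] * 10 + [-1] * 10 + [1] * 60 + [-1] * 15 + [0] * 10
        assert commute_minutes(labels, home_id=0, work_ids={1}) == 25

    def test_intermediate_dwell_breaks_segment(self):
        labels = [0] * 10 + [-1] * 5 + [2] * 30 + [-1] * 5 + [1] * 60
        assert commute_minutes(labels, home_id=0, work_ids={1}) == 0


class TestEntropyVariance:
    def test_single_cluster_entropy_zero(self):
        assert location_entropy([120.0]) == 0.0

    def test_uniform_four_clusters(self):
        assert location_entropy([10, 10, 10, 10]) == pytest.approx(math.log(4))

    def test_hand_computed_split(self):
        expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert location_entropy([300, 100]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5623, abs=1e-4)

    def test_all_zero_minutes_rejected(self):
        with pytest.raises(ValueError):
            location_entropy([0.0, 0.0])

    @given(st.lists(st.floats(min_value=0, max_value=1e5), min_size=1, max_size=20))
    def test_entropy_bounds(self, minutes):
        if sum(minutes) <= 0:
            return
        h = location_entropy(minutes)
        k = sum(1 for m in minutes if m > 0)
        assert -1e-12 <= h <= math.log(k) + 1e-12

    def test_identical_points_zero_variance(self):
        assert location_variance([40.0] * 5, [-75.0] * 5) == 0.0

    def test_hand_computable_variance(self):
        assert location_variance([0, 0], [0, 2]) == pytest.approx(1.0)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        lat, lon = rng.normal(40, 0.01, 50), rng.normal(-75, 0.02, 50)

        def two_pass(x):
            m = sum(x) / len(x)
            return sum((v - m) ** 2 for v in x) / len(x)

        assert location_variance(lat, lon) == pytest.approx(two_pass(lat) + two_pass(lon), abs=1e-12)

    def test_single_point_is_missing(self):
        assert np.isnan(location_variance([40.0], [-75.0]))


def test_anchor_recovery_on_synthetic_trajectories():
    """Home and work labels recover the generating anchors for >= 95% of
    participants at default jitter and clustering parameters."""
    from phenoweek import CohortConfig, MissingnessConfig
    from phenoweek.config import LocationConfig
    from phenoweek.simulate import iter_participants

    cfg = CohortConfig(n_participants=20, n_weeks=3, seed=77, missingness=MissingnessConfig.none())
    loc_cfg = LocationConfig()
    ok = 0
    for pdata in iter_participants(cfg):
        loc = pdata.streams["location"]
        lat, lon = loc["lat"].to_numpy(), loc["lon"].to_numpy()
        ts = pd.DatetimeIndex(loc["timestamp"])
        labels = cluster_locations(lat, lon, loc_cfg.eps_m, loc_cfg.min_samples, grid_m=loc_cfg.grid_m)
        home = label_home(labels, ts)
        works = label_work(labels, ts, home)
        cent = cluster_centroids(lat, lon, labels)
        anchors = pdata.place_tags
        home_anchor = anchors[anchors["tags"] == "residential"].iloc[0]
        work_anchor = anchors[anchors["tags"] == "office"].iloc[0]

        def near(cluster, anchor, tol_m=60.0):
            dlat = (cent.loc[cluster, "lat"] - anchor["lat"]) * M_PER_DEG
            dlon = (cent.loc[cluster, "lon"] - anchor["lon"]) * M_PER_DEG * math.cos(math.radians(anchor["lat"]))
            return math.hypot(dlat, dlon) <= tol_m

        if home is not None and near(home, home_anchor) and any(near(w, work_anchor) for w in works):
            ok += 1
    assert ok >= 19  # >= 95% of 20
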