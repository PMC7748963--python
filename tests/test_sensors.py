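"""Passive-sensing feature extraction: windows, sessions, similarity, sleep."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stopsense.sensors import (
    AnalysisWindow,
    EventStreams,
    InputError,
    PoiTable,
    activity_features,
    battery_features,
    build_feature_table,
    call_features,
    infer_sleep,
    clip_sleep_durations,
    location_categories,
    location_flags,
    network_features,
    noise_features,
    phone_use_features,
    segment_sessions,
    set_similarity,
    time_features,
    wifi_similarity,
)

W = AnalysisWindow("p", 3600.0)  # window [0, 3600)


def _screen(*events):
    return pd.DataFrame(events, columns=["ts", "event"])


class TestSessions:
    def test_pairing(self):
        s = segment_sessions(
            _screen((0, "unlock"), (40, "lock"), (100, "unlock"), (115, "lock"))
        )
        assert list(s["duration_s"]) == [40, 15]

    def test_empty(self):
        assert len(segment_sessions(_screen())) == 0

    def test_orphan_lock_ignored_trailing_unlock_closed(self):
        s = segment_sessions(
            _screen((5, "lock"), (10, "unlock"), (20, "lock"), (30, "unlock"))
        )
        assert list(s["start_s"]) == [10, 30]
        assert list(s["end_s"]) == [20, 30]  # trailing closed at stream end

    def test_unsorted_rejected(self):
        with pytest.raises(InputError):
            segment_sessions(_screen((10, "unlock"), (5, "lock")))


def _sessions(*pairs):
    df = pd.DataFrame(pairs, columns=["start_s", "end_s"])
    df["duration_s"] = df["end_s"] - df["start_s"]
    return df


class TestPhoneUse:
    def test_toy_statistics(self):
        f = phone_use_features(W, _sessions((100, 110), (200, 245), (300, 500)))
        assert f["phone.burstiness"] == 3
        assert f["phone.n_short"] == 1
        assert f["phone.total_duration"] == 255
        assert f["phone.mean_duration"] == 85
        assert f["phone.mean_gap"] == pytest.approx(((200 - 110) + (300 - 245)) / 2)

    def test_empty_window(self):
        f = phone_use_features(W, _sessions())
        assert f["phone.burstiness"] == 0
        assert math.isnan(f["phone.mean_duration"])
        assert math.isnan(f["phone.sd_duration"])

    def test_thirty_second_session_not_short(self):
        f = phone_use_features(W, _sessions((0, 30.0), (40, 69.9)))
        assert f["phone.n_short"] == 1  # 30.0 s is not short; 29.9 s is

    def test_edge_clipping_counts_once(self):
        # session straddling the window start contributes clipped duration
        f = phone_use_features(W, _sessions((-100, 50)))
        assert f["phone.burstiness"] == 1
        assert f["phone.total_duration"] == 50


class TestCalls:
    def test_counts_and_means(self):
        calls = pd.DataFrame(
            [("in", 100, 60.0), ("in", 500, 120.0), ("out", 900, 30.0)],
            columns=["direction", "start", "duration"],
        )
        f = call_features(W, calls)
        assert f["call.n_incoming"] == 2
        assert f["call.mean_duration_incoming"] == 90
        assert f["call.total_duration_outgoing"] == 30

    def test_no_calls(self):
        f = call_features(W, pd.DataFrame(columns=["direction", "start", "duration"]))
        assert f["call.n_incoming"] == 0
        assert math.isnan(f["call.mean_duration_incoming"])

    def test_half_open_boundary(self):
        calls = pd.DataFrame(
            [("in", 3600.0, 60.0)], columns=["direction", "start", "duration"]
        )
        assert call_features(W, calls)["call.n_incoming"] == 0


class TestBattery:
    def _bat(self, *rows):
        return pd.DataFrame(rows, columns=["ts", "level", "charging"])

    def test_discharge_rate(self):
        f = battery_features(W, self._bat((0, 80.0, False), (3599, 74.0, False)))
        assert f["battery.discharge_rate"] == pytest.approx(6.0 / 3599)

    def test_constant_level(self):
        f = battery_features(W, self._bat((0, 50.0, False), (1800, 50.0, False)))
        assert f["battery.discharge_rate"] == 0.0

    def test_single_sample_missing_rates(self):
        f = battery_features(W, self._bat((0, 50.0, True)))
        assert math.isnan(f["battery.discharge_rate"])
        assert f["battery.n_charging_episodes"] == 1

    def test_charging_time_share(self):
        # charging state persists until the first not-charging sample
        f = battery_features(
            W,
            self._bat((0, 50.0, True), (900, 55.0, True), (2700, 54.0, False),
                      (3599, 53.0, False)),
        )
        assert f["battery.pct_charging"] == pytest.approx(100 * 2700 / 3599)
        assert f["battery.total_charging_s"] == pytest.approx(2700)
        # rates use consecutive same-state pairs only
        assert f["battery.charge_rate"] == pytest.approx(5.0 / 900)
        assert f["battery.discharge_rate"] == pytest.approx(1.0 / 899)


class TestActivity:
    def _act(self, *rows):
        return pd.DataFrame(rows, columns=["ts", "label", "accel", "steps", "distance"])

    def test_all_stationary(self):
        f = activity_features(W, self._act((0, "stationary", 1.0, 0, 0)))
        assert f["activity.pct_stationary"] == 100.0
        assert f["activity.pct_nonstationary"] == 0.0

    def test_half_and_half(self):
        f = activity_features(
            W,
            self._act(
                *[(600 * k, "stationary", 1.0, 10, 5) for k in range(3)],
                *[(1800 + 600 * k, "walking", 1.2, 50, 40) for k in range(3)],
            ),
        )
        assert f["activity.pct_stationary"] == pytest.approx(50.0)
        assert f["activity.pct_walking"] == pytest.approx(50.0)
        assert f["activity.steps"] == 3 * 10 + 3 * 50

    def test_constant_accel_sd_zero(self):
        f = activity_features(
            W, self._act((0, "walking", 1.5, 0, 0), (600, "walking", 1.5, 0, 0))
        )
        assert f["activity.accel_sd"] == 0.0

    def test_long_gap_unlabeled(self):
        # 15-min persistence cap: a lone early sample labels at most 900 s
        f = activity_features(
            W, self._act((0, "walking", 1.0, 0, 0), (3000, "stationary", 1.0, 0, 0))
        )
        # walking 900 s, stationary 600 s (3000 -> 3600)
        assert f["activity.pct_walking"] == pytest.approx(100 * 900 / 1500)


class TestNoise:
    def test_three_sample_stats(self):
        noise = pd.DataFrame(
            [(0, 100.0, 40.0, 0.1), (10, 100.0, 50.0, 0.1), (20, 100.0, 60.0, 0.1)],
            columns=["ts", "frequency", "db", "rms"],
        )
        f = noise_features(W, noise)
        assert f["noise.db_mean"] == 50
        assert f["noise.db_median"] == 50
        assert f["noise.db_sd"] == pytest.approx(10.0)  # sample SD
        assert f["noise.freq_sd"] == 0.0

    def test_empty_missing(self):
        f = noise_features(W, pd.DataFrame(columns=["ts", "frequency", "db", "rms"]))
        assert all(math.isnan(v) for v in f.values())


class TestNetwork:
    def _net(self, *rows):
        return pd.DataFrame(rows, columns=["ts", "state"])

    def test_always_wifi(self):
        f = network_features(W, self._net((0, "wifi"), (600, "wifi"), (1200, "wifi"),
                                          (1800, "wifi"), (2400, "wifi"), (3000, "wifi")))
        assert f["network.pct_wifi"] == 100.0
        assert f["network.pct_connected"] == 100.0

    def test_mobile_then_wifi(self):
        rows = [(i * 300, "mobile" if i * 300 < 900 else "wifi") for i in range(12)]
        f = network_features(W, self._net(*rows))
        assert f["network.pct_mobile"] == pytest.approx(25.0)
        assert f["network.pct_wifi"] == pytest.approx(75.0)

    def test_missing_without_samples(self):
        f = network_features(W, self._net())
        assert math.isnan(f["network.pct_wifi"])

    def test_shares_partition(self):
        rows = [(i * 400, ["wifi", "mobile", "none"][i % 3]) for i in range(9)]
        f = network_features(W, self._net(*rows))
        total = f["network.pct_wifi"] + f["network.pct_mobile"] + f["network.pct_none"]
        assert total == pytest.approx(100.0)


class TestSimilarity:
    METRICS = ("jaccard", "dice", "kulczynski2", "ochiai")

    def test_identity_and_disjoint(self):
        for m in self.METRICS:
            assert set_similarity({"a", "b"}, {"a", "b"}, m) == 1.0
            assert set_similarity({"a"}, {"b", "c"}, m) == 0.0

    def test_hand_evaluated_overlap(self):
        a, b = {"a", "b"}, {"b", "c"}
        assert set_similarity(a, b, "jaccard") == pytest.approx(1 / 3)
        assert set_similarity(a, b, "dice") == pytest.approx(1 / 2)
        assert set_similarity(a, b, "kulczynski2") == pytest.approx(1 / 2)
        assert set_similarity(a, b, "ochiai") == pytest.approx(1 / 2)

    def test_empty_conventions(self):
        for m in self.METRICS:
            assert math.isnan(set_similarity(set(), set(), m))
            assert set_similarity(set(), {"a"}, m) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(
        st.sets(st.integers(0, 20), max_size=8),
        st.sets(st.integers(0, 20), max_size=8),
    )
    def test_symmetry_and_range(self, a, b):
        for m in self.METRICS:
            v = set_similarity(a, b, m)
            w = set_similarity(b, a, m)
            if math.isnan(v):
                assert not a and not b and math.isnan(w)
            else:
                assert v == pytest.approx(w)
                assert 0.0 <= v <= 1.0

    def test_relabeling_invariance(self):
        a, b = {"x", "y", "z"}, {"y", "z", "w"}
        ra, rb = {1, 2, 3}, {2, 3, 4}  # same overlap structure
        for m in self.METRICS:
            assert set_similarity(a, b, m) == set_similarity(ra, rb, m)


class TestLocation:
    def test_radius_rule(self):
        # venue ~30 m north is inside the 50 m radius, ~70 m is not
        poi = PoiTable(
            venues=pd.DataFrame(
                [
                    (40.0 + 30 / 111320, -75.0, "Residence"),
                    (40.0 + 70 / 111320, -75.0, "Nightlife Spot"),
                ],
                columns=["lat", "lon", "category"],
            )
        )
        gps = pd.DataFrame([(100.0, 40.0, -75.0)], columns=["ts", "lat", "lon"])
        assert location_categories(W, gps, poi) == {"Residence"}

    def test_no_fixes(self):
        poi = PoiTable()
        gps = pd.DataFrame(columns=["ts", "lat", "lon"])
        assert location_categories(W, gps, poi) == set()

    def test_flags(self):
        poi = PoiTable()
        f = location_flags(set(), {"Outdoors & Recreation"}, poi)
        assert f["loc.outdoors_recreation_previous"] == 1.0
        assert f["loc.outdoors_recreation_current"] == 0.0
        assert all(v in (0.0, 1.0) for v in f.values())


class TestWifi:
    def test_identical_and_disjoint(self):
        wifi = pd.DataFrame(
            [(-3000, ("a", "b")), (600, ("a", "b"))], columns=["ts", "ssids"]
        )
        f = wifi_similarity(W, wifi)
        assert f["wifi.jaccard"] == 1.0
        wifi2 = pd.DataFrame(
            [(-3000, ("a", "b")), (600, ("c", "d"))], columns=["ts", "ssids"]
        )
        assert wifi_similarity(W, wifi2)["wifi.jaccard"] == 0.0


NOON = 1704110400.0  # 2024-01-01 12:00 UTC


class TestSleep:
    def test_longest_night_gap(self):
        # hourly 2-min phone use 12:00-23:00, then nothing until 07:00
        pairs = [(NOON + h * 3600, NOON + h * 3600 + 120) for h in range(12)]
        pairs += [(NOON + (19 + h) * 3600, NOON + (19 + h) * 3600 + 120)
                  for h in range(5)]  # 07:00..11:00 next day
        res = infer_sleep(_sessions(*pairs), NOON)
        assert res is not None
        onset, offset, dur = res
        assert onset == NOON + 11 * 3600 + 120  # last use ended 23:02
        assert offset == NOON + 19 * 3600       # first use 07:00
        assert dur == pytest.approx((offset - onset) / 3600)

    def test_continuous_use_no_sleep(self):
        pairs = [(NOON + k * 1800, NOON + k * 1800 + 60) for k in range(48)]
        assert infer_sleep(_sessions(*pairs), NOON) is None

    def test_outlier_clipping(self):
        durs = pd.Series([7.0, 7.5, 8.0, 7.2, 7.8, 20.0])
        clipped = clip_sleep_durations(durs)
        mu, sd = durs.mean(), durs.std(ddof=1)
        assert clipped.iloc[-1] == pytest.approx(mu + 2 * sd)
        assert (clipped.iloc[:-1] == durs.iloc[:-1]).all()


class TestTime:
    def test_epoch_oracle(self):
        w = AnalysisWindow("p", 1577880000.0)  # 2020-01-01 12:00 UTC, Wednesday
        f = time_features(w, "UTC")
        assert f["time.hour"] == 12
        assert f["time.day_of_week"] == 2
        assert f["time.weekend"] == 0.0

    def test_weekend_and_timezone(self):
        sunday_noon = 1578225600.0  # 2020-01-05 12:00 UTC
        f = time_features(AnalysisWindow("p", sunday_noon), "UTC")
        assert f["time.weekend"] == 1.0
        # same instant is 7 AM in New York
        f2 = time_features(AnalysisWindow("p", sunday_noon), "America/New_York")
        assert f2["time.hour"] == 7


class TestFeatureTable:
    def test_empty_prompts(self):
        tab = build_feature_table(EventStreams(), [], PoiTable())
        assert len(tab) == 0

    def test_row_count_columns_and_purity(self, small_cohort):
        pid = "p00"
        prompts = small_cohort.prompts.query("participant_id == @pid")["end_s"].to_numpy()[:5]
        t1 = build_feature_table(small_cohort.streams[pid], prompts, small_cohort.poi, pid)
        t2 = build_feature_table(small_cohort.streams[pid], prompts, small_cohort.poi, pid)
        assert len(t1) == len(prompts)
        assert list(t1.columns) == list(t2.columns)
        pd.testing.assert_frame_equal(t1, t2)

    def test_half_open_no_double_count(self):
        # a call exactly at the boundary belongs to the later window only
        calls = pd.DataFrame([("in", 3600.0, 60.0)], columns=["direction", "start", "duration"])
        w1 = AnalysisWindow("p", 3600.0)
        w2 = AnalysisWindow("p", 7200.0)
        assert call_features(w1, calls)["call.n_incoming"] == 0
        assert call_features(w2, calls)["call.n_incoming"] == 1
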