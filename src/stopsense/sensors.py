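"""Hourly passive-sensing feature extraction.

Turns raw per-participant event streams (screen lock/unlock, calls,
battery, activity, GPS + nearby points of interest, Wi-Fi scans, ambient
noise, network state) into the per-hour feature vector aligned to each
stop-signal-task prompt: the analysis window is the hour before the prompt,
[t-1h, t), and similarity/location features also look at the previous hour
[t-2h, t-1h).

All windows are half-open: an event stamped exactly at the window end
belongs to the next window.  Missing features are emitted as NaN and are
never imputed here.

Stream layouts (pandas DataFrames, timestamps in Unix epoch seconds UTC):

=========  =======================================================
screen     ts, event ("lock"/"unlock")
calls      direction ("in"/"out"), start, duration
battery    ts, level (0-100), charging (bool)
activity   ts, label, accel, steps, distance
gps        ts, lat, lon
wifi       ts, ssids (iterable of str)
noise      ts, frequency, db, rms
network    ts, state ("wifi"/"mobile"/"none")
=========  =======================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

__all__ = [
    "EventStreams",
    "AnalysisWindow",
    "PoiTable",
    "CATEGORY_GROUPS",
    "segment_sessions",
    "clip_sessions",
    "phone_use_features",
    "call_features",
    "battery_features",
    "activity_features",
    "noise_features",
    "network_features",
    "set_similarity",
    "location_categories",
    "location_flags",
    "wifi_ssid_set",
    "wifi_similarity",
    "infer_sleep",
    "clip_sleep_durations",
    "time_features",
    "build_feature_table",
]

WINDOW_S = 3600.0
SHORT_SESSION_S = 30.0          # strict: a 30.0 s session is not short
STATE_GAP_MAX_S = 900.0         # sampled states persist at most 15 min
POI_RADIUS_M = 50.0             # strict: venues at exactly 50 m excluded
ACTIVITY_LABELS = ("stationary", "walking", "running", "automotive", "cycling")

# Venue category -> model category group (the six groups used as flags).
CATEGORY_GROUPS = {
    "Outdoors & Recreation": "outdoors_recreation",
    "Residence": "residence",
    "Arts & Entertainment": "arts_entertainment",
    "Professional & Other Places": "professional_other",
    "College & University": "college_university",
    "Nightlife Spot": "nightlife",
}


class InputError(ValueError):
    """Raised for malformed event streams (e.g. unsorted timestamps)."""


@dataclass
class EventStreams:
    """Typed raw sensor logs for one participant."""

    screen: pd.DataFrame = None
    calls: pd.DataFrame = None
    battery: pd.DataFrame = None
    activity: pd.DataFrame = None
    gps: pd.DataFrame = None
    wifi: pd.DataFrame = None
    noise: pd.DataFrame = None
    network: pd.DataFrame = None

    _SCHEMAS = {
        "screen": ["ts", "event"],
        "calls": ["direction", "start", "duration"],
        "battery": ["ts", "level", "charging"],
        "activity": ["ts", "label", "accel", "steps", "distance"],
        "gps": ["ts", "lat", "lon"],
        "wifi": ["ts", "ssids"],
        "noise": ["ts", "frequency", "db", "rms"],
        "network": ["ts", "state"],
    }

    def __post_init__(self) -> None:
        for name, cols in self._SCHEMAS.items():
            df = getattr(self, name)
            if df is None:
                df = pd.DataFrame({c: [] for c in cols})
                setattr(self, name, df)
            tcol = "start" if name == "calls" else "ts"
            if len(df) and not df[tcol].is_monotonic_increasing:
                raise InputError(f"{name} stream is not time-sorted")


@dataclass(frozen=True)
class AnalysisWindow:
    """One-hour window ending at an SST prompt; half-open [start_s, end_s)."""

    participant_id: str
    end_s: float

    @property
    def start_s(self) -> float:
        return self.end_s - WINDOW_S

    @property
    def previous(self) -> "AnalysisWindow":
        return AnalysisWindow(self.participant_id, self.end_s - WINDOW_S)


@dataclass
class PoiTable:
    """Offline point-of-interest table: venue coordinates and categories."""

    venues: pd.DataFrame = None  # columns: lat, lon, category
    groups: dict = field(default_factory=lambda: dict(CATEGORY_GROUPS))

    def __post_init__(self) -> None:
        if self.venues is None:
            self.venues = pd.DataFrame({"lat": [], "lon": [], "category": []})

    def nearby_categories(self, lat: float, lon: float) -> set[str]:
        if not len(self.venues):
            return set()
        d = haversine_m(
            lat, lon, self.venues["lat"].to_numpy(), self.venues["lon"].to_numpy()
        )
        return set(self.venues.loc[d < POI_RADIUS_M, "category"])


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters on a 6371 km sphere."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 6371000.0 * 2 * np.arcsin(np.sqrt(a))


# ---------------------------------------------------------------------------
# phone use


def segment_sessions(screen: pd.DataFrame) -> pd.DataFrame:
    """Pair screen unlock events with the next lock into phone-use sessions.

    An unmatched trailing unlock is closed at the last event's timestamp;
    a lock with no prior unlock is ignored.
    """
    if len(screen) and not screen["ts"].is_monotonic_increasing:
        raise InputError("screen events not time-sorted")
    starts, ends = [], []
    open_t = None
    for ts, ev in zip(screen["ts"], screen["event"]):
        if ev == "unlock" and open_t is None:
            open_t = ts
        elif ev == "lock" and open_t is not None:
            starts.append(open_t)
            ends.append(ts)
            open_t = None
    if open_t is not None:
        starts.append(open_t)
        ends.append(float(screen["ts"].iloc[-1]))
    out = pd.DataFrame({"start_s": starts, "end_s": ends})
    out["duration_s"] = out["end_s"] - out["start_s"]
    return out


def clip_sessions(sessions: pd.DataFrame, start_s: float, end_s: float) -> pd.DataFrame:
    """Intersect sessions with [start_s, end_s); drop empty intersections."""
    s = sessions["start_s"].clip(lower=start_s)
    e = sessions["end_s"].clip(upper=end_s)
    keep = e > s
    out = pd.DataFrame({"start_s": s[keep], "end_s": e[keep]})
    out["duration_s"] = out["end_s"] - out["start_s"]
    return out.reset_index(drop=True)


def phone_use_features(window: AnalysisWindow, sessions: pd.DataFrame) -> dict:
    """Burstiness, short-session count and duration/gap statistics.

    Sessions spanning a window edge contribute only their in-window portion
    to duration features but still count once toward burstiness.
    """
    w = clip_sessions(sessions, window.start_s, window.end_s)
    d = w["duration_s"].to_numpy()
    gaps = (w["start_s"].to_numpy()[1:] - w["end_s"].to_numpy()[:-1]) if len(w) > 1 else np.array([])
    return {
        "phone.burstiness": float(len(w)),
        "phone.n_short": float((d < SHORT_SESSION_S).sum()),
        "phone.total_duration": float(d.sum()) if len(d) else np.nan,
        "phone.mean_duration": float(d.mean()) if len(d) else np.nan,
        "phone.sd_duration": float(d.std(ddof=1)) if len(d) > 1 else np.nan,
        "phone.mean_gap": float(gaps.mean()) if len(gaps) else np.nan,
        "phone.sd_gap": float(gaps.std(ddof=1)) if len(gaps) > 1 else np.nan,
    }


def call_features(window: AnalysisWindow, calls: pd.DataFrame) -> dict:
    """Counts and mean durations of incoming/outgoing calls (by start time)."""
    m = (calls["start"] >= window.start_s) & (calls["start"] < window.end_s)
    w = calls[m]
    out: dict[str, float] = {}
    for direction, name in (("in", "incoming"), ("out", "outgoing")):
        dur = w.loc[w["direction"] == direction, "duration"].to_numpy(dtype=float)
        out[f"call.n_{name}"] = float(len(dur))
        out[f"call.mean_duration_{name}"] = float(dur.mean()) if len(dur) else np.nan
    out["call.total_duration_outgoing"] = (
        float(w.loc[w["direction"] == "out", "duration"].sum())
        if (w["direction"] == "out").any()
        else np.nan
    )
    return out


def battery_features(window: AnalysisWindow, battery: pd.DataFrame) -> dict:
    """Charging frequency/time and battery level change rates.

    Change rates are computed over consecutive same-state sample pairs; the
    discharging rate is reported as a positive drain magnitude
    (level units per second).
    """
    m = (battery["ts"] >= window.start_s) & (battery["ts"] < window.end_s)
    w = battery[m]
    out = {
        "battery.n_charging_episodes": np.nan,
        "battery.pct_charging": np.nan,
        "battery.total_charging_s": np.nan,
        "battery.charge_rate": np.nan,
        "battery.discharge_rate": np.nan,
    }
    if not len(w):
        return out
    charging = w["charging"].to_numpy(dtype=bool)
    episodes = int(charging[0]) + int((charging[1:] & ~charging[:-1]).sum())
    out["battery.n_charging_episodes"] = float(episodes)
    if len(w) < 2:
        return out
    ts = w["ts"].to_numpy(dtype=float)
    level = w["level"].to_numpy(dtype=float)
    dt = np.diff(ts)
    same = charging[:-1] == charging[1:]
    charge_time = float(dt[charging[:-1]].sum())
    total_time = float(dt.sum())
    out["battery.total_charging_s"] = charge_time
    out["battery.pct_charging"] = 100.0 * charge_time / total_time if total_time else np.nan
    rate = np.diff(level) / dt
    cpairs = same & charging[:-1]
    dpairs = same & ~charging[:-1]
    if cpairs.any():
        out["battery.charge_rate"] = float(rate[cpairs].mean())
    if dpairs.any():
        out["battery.discharge_rate"] = float(-rate[dpairs].mean())
    return out


def _state_durations(
    ts: np.ndarray, states: np.ndarray, start_s: float, end_s: float
) -> dict:
    """Time per state in [start_s, end_s) with persist-to-next-sample rule.

    A sample's state holds until the next sample, for at most
    ``STATE_GAP_MAX_S``; longer gaps are unlabeled time.  The sample
    preceding the window contributes its clipped tail.
    """
    total: dict = {}
    if not len(ts):
        return total
    nxt = np.append(ts[1:], np.inf)
    seg_end = np.minimum(np.minimum(nxt, ts + STATE_GAP_MAX_S), end_s)
    seg_start = np.clip(ts, start_s, end_s)
    seg_end = np.clip(seg_end, start_s, end_s)
    dur = seg_end - seg_start
    for s, d in zip(states, dur):
        if d > 0:
            total[s] = total.get(s, 0.0) + float(d)
    return total


def activity_features(window: AnalysisWindow, activity: pd.DataFrame) -> dict:
    """Time shares per activity label plus steps, distance and acceleration."""
    out: dict[str, float] = {}
    durs = _state_durations(
        activity["ts"].to_numpy(dtype=float),
        activity["label"].to_numpy(),
        window.start_s,
        window.end_s,
    )
    labeled = sum(durs.get(l, 0.0) for l in ACTIVITY_LABELS)
    for l in ACTIVITY_LABELS:
        out[f"activity.pct_{l}"] = 100.0 * durs.get(l, 0.0) / labeled if labeled else np.nan
    out["activity.pct_nonstationary"] = (
        100.0 - out["activity.pct_stationary"] if labeled else np.nan
    )
    m = (activity["ts"] >= window.start_s) & (activity["ts"] < window.end_s)
    w = activity[m]
    out["activity.steps"] = float(w["steps"].sum()) if len(w) else np.nan
    out["activity.distance_m"] = float(w["distance"].sum()) if len(w) else np.nan
    acc = w["accel"].to_numpy(dtype=float)
    out["activity.accel_mean"] = float(acc.mean()) if len(acc) else np.nan
    out["activity.accel_sd"] = float(acc.std(ddof=1)) if len(acc) > 1 else np.nan
    return out


def noise_features(window: AnalysisWindow, noise: pd.DataFrame) -> dict:
    """Mean/median/SD of ambient-noise frequency, loudness (dB) and RMS power."""
    m = (noise["ts"] >= window.start_s) & (noise["ts"] < window.end_s)
    w = noise[m]
    out = {}
    for col, name in (("frequency", "freq"), ("db", "db"), ("rms", "rms")):
        x = w[col].to_numpy(dtype=float)
        out[f"noise.{name}_mean"] = float(x.mean()) if len(x) else np.nan
        out[f"noise.{name}_median"] = float(np.median(x)) if len(x) else np.nan
        out[f"noise.{name}_sd"] = float(x.std(ddof=1)) if len(x) > 1 else np.nan
    return out


def network_features(window: AnalysisWindow, network: pd.DataFrame) -> dict:
    """Time shares connected via Wi-Fi, mobile, or not connected."""
    durs = _state_durations(
        network["ts"].to_numpy(dtype=float),
        network["state"].to_numpy(),
        window.start_s,
        window.end_s,
    )
    labeled = sum(durs.values())
    out = {}
    for state in ("wifi", "mobile", "none"):
        out[f"network.pct_{state}"] = (
            100.0 * durs.get(state, 0.0) / labeled if labeled else np.nan
        )
    out["network.pct_connected"] = (
        out["network.pct_wifi"] + out["network.pct_mobile"] if labeled else np.nan
    )
    return out


# ---------------------------------------------------------------------------
# similarity and location


def set_similarity(a: set, b: set, metric: str) -> float:
    """Binary set-overlap coefficient in [0, 1].

    jaccard |A∩B|/|A∪B|; dice 2|A∩B|/(|A|+|B|);
    kulczynski2 (|A∩B|/|A| + |A∩B|/|B|)/2; ochiai |A∩B|/sqrt(|A||B|).
    Both sets empty -> NaN; exactly one empty -> 0.
    """
    a, b = set(a), set(b)
    if not a and not b:
        return float("nan")
    if not a or not b:
        return 0.0
    inter = len(a & b)
    if metric == "jaccard":
        return inter / len(a | b)
    if metric == "dice":
        return 2 * inter / (len(a) + len(b))
    if metric == "kulczynski2":
        return 0.5 * (inter / len(a) + inter / len(b))
    if metric == "ochiai":
        return inter / math.sqrt(len(a) * len(b))
    raise ValueError(f"unknown metric {metric!r}")


SIMILARITY_METRICS = ("jaccard", "dice", "kulczynski2", "ochiai")


def location_categories(
    window: AnalysisWindow, gps: pd.DataFrame, poi: PoiTable
) -> set[str]:
    """Distinct venue categories within 50 m of any in-window GPS fix."""
    m = (gps["ts"] >= window.start_s) & (gps["ts"] < window.end_s)
    cats: set[str] = set()
    for _, row in gps[m].iterrows():
        cats |= poi.nearby_categories(row["lat"], row["lon"])
    return cats


def location_flags(current: set[str], previous: set[str], poi: PoiTable) -> dict:
    """Binary flags per category group for the past hour and the hour before."""
    out = {}
    cur_groups = {poi.groups[c] for c in current if c in poi.groups}
    prev_groups = {poi.groups[c] for c in previous if c in poi.groups}
    for group in sorted(set(CATEGORY_GROUPS.values())):
        out[f"loc.{group}_current"] = float(group in cur_groups)
        out[f"loc.{group}_previous"] = float(group in prev_groups)
    return out


def wifi_ssid_set(window: AnalysisWindow, wifi: pd.DataFrame) -> set[str]:
    m = (wifi["ts"] >= window.start_s) & (wifi["ts"] < window.end_s)
    out: set[str] = set()
    for ssids in wifi.loc[m, "ssids"]:
        out |= set(ssids)
    return out


def wifi_similarity(window: AnalysisWindow, wifi: pd.DataFrame) -> dict:
    """Overlap of SSID presence sets between the window and the previous hour."""
    cur = wifi_ssid_set(window, wifi)
    prev = wifi_ssid_set(window.previous, wifi)
    return {
        f"wifi.{m}": set_similarity(cur, prev, m) for m in SIMILARITY_METRICS
    }


def location_similarity(cur: set[str], prev: set[str]) -> dict:
    return {f"loc.{m}": set_similarity(cur, prev, m) for m in SIMILARITY_METRICS}


# ---------------------------------------------------------------------------
# sleep


MIN_SLEEP_GAP_S = 3 * 3600.0  # shorter phone-free gaps are not sleep


def infer_sleep(
    sessions: pd.DataFrame, day_noon_s: float, tz: str = "UTC"
) -> tuple[float, float, float] | None:
    """Infer one night's sleep from phone-use gaps in a noon-to-noon frame.

    Within the frame starting at ``day_noon_s`` (local noon), the longest
    gap of at least 3 h between consecutive phone-use sessions that
    overlaps the 9 PM - 11 AM night span defines sleep: onset is the end of
    the last use before the gap, offset the start of the first use after.
    Returns (onset_s, offset_s, duration_h) or None if no qualifying gap.
    """
    frame_end = day_noon_s + 24 * 3600.0
    night_start = day_noon_s + 9 * 3600.0       # 9 PM local
    night_end = day_noon_s + 23 * 3600.0        # 11 AM next day
    w = clip_sessions(sessions, day_noon_s, frame_end)
    if len(w) < 2:
        return None
    ends = w["end_s"].to_numpy()[:-1]
    starts = w["start_s"].to_numpy()[1:]
    gaps = starts - ends
    overlap = (starts > night_start) & (ends < night_end)
    ok = (gaps >= MIN_SLEEP_GAP_S) & overlap
    if not ok.any():
        return None
    i = int(np.argmax(np.where(ok, gaps, -np.inf)))
    onset, offset = float(ends[i]), float(starts[i])
    return onset, offset, (offset - onset) / 3600.0


def clip_sleep_durations(durations_h: pd.Series) -> pd.Series:
    """Replace durations outside mean ± 2 SD by the nearer boundary."""
    x = durations_h.astype(float)
    if x.notna().sum() < 2:
        return x
    mu, sd = x.mean(), x.std(ddof=1)
    return x.clip(lower=mu - 2 * sd, upper=mu + 2 * sd)


# ---------------------------------------------------------------------------
# time


def time_features(window: AnalysisWindow, tz: str = "UTC") -> dict:
    """Hour of day, day of week (Monday=0) and weekend flag at window end."""
    dt = datetime.fromtimestamp(window.end_s, tz=timezone.utc).astimezone(ZoneInfo(tz))
    return {
        "time.hour": float(dt.hour),
        "time.day_of_week": float(dt.weekday()),
        "time.weekend": float(dt.weekday() >= 5),
    }


# ---------------------------------------------------------------------------
# assembly


def build_feature_table(
    streams: EventStreams,
    prompts: "pd.Series | np.ndarray | list[float]",
    poi: PoiTable | None = None,
    participant_id: str = "p0",
    tz: str = "UTC",
) -> pd.DataFrame:
    """One feature row per SST prompt time.

    Computes every per-window feature family for the hour before each
    prompt, plus previous-window location/Wi-Fi similarity and per-night
    sleep (attributed to the noon-to-noon frame ending on the prompt's
    local date, with per-participant outlier clipping).
    """
    poi = poi or PoiTable()
    sessions = segment_sessions(streams.screen)
    rows = []
    tzinfo = ZoneInfo(tz)

    # per-night sleep, indexed by local date of the morning
    sleep_by_date: dict = {}
    if len(prompts):
        t0 = float(min(prompts)) - 2 * 24 * 3600
        t1 = float(max(prompts)) + 24 * 3600
        d = datetime.fromtimestamp(t0, tz=timezone.utc).astimezone(tzinfo)
        noon = d.replace(hour=12, minute=0, second=0, microsecond=0)
        while noon.timestamp() < t1:
            res = infer_sleep(sessions, noon.timestamp(), tz)
            morning = (noon + pd.Timedelta(days=1)).date()
            sleep_by_date[morning] = res
            noon = noon + pd.Timedelta(days=1)
    raw_durs = pd.Series(
        {d: (r[2] if r else np.nan) for d, r in sleep_by_date.items()}, dtype=float
    )
    clipped = clip_sleep_durations(raw_durs) if len(raw_durs) else raw_durs

    for t in prompts:
        w = AnalysisWindow(participant_id, float(t))
        feats: dict[str, float] = {"participant_id": participant_id, "end_s": float(t)}
        feats.update(phone_use_features(w, sessions))
        feats.update(call_features(w, streams.calls))
        feats.update(battery_features(w, streams.battery))
        feats.update(activity_features(w, streams.activity))
        feats.update(noise_features(w, streams.noise))
        feats.update(network_features(w, streams.network))
        cur = location_categories(w, streams.gps, poi)
        prev = location_categories(w.previous, streams.gps, poi)
        feats.update(location_similarity(cur, prev))
        feats.update(location_flags(cur, prev, poi))
        feats.update(wifi_similarity(w, streams.wifi))
        date = datetime.fromtimestamp(float(t), tz=timezone.utc).astimezone(tzinfo).date()
        res = sleep_by_date.get(date)
        if res is not None and res is not False and not (
            isinstance(res, float) and np.isnan(res)
        ) and res:
            feats["sleep.onset_s"] = res[0]
            feats["sleep.offset_s"] = res[1]
            feats["sleep.duration_h"] = float(clipped.get(date, np.nan))
        else:
            feats["sleep.onset_s"] = np.nan
            feats["sleep.offset_s"] = np.nan
            feats["sleep.duration_h"] = np.nan
        feats.update(time_features(w, tz))
        rows.append(feats)
    cols = list(rows[0].keys()) if rows else ["participant_id", "end_s"]
    return pd.DataFrame(rows, columns=cols)
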