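"""Synthetic cohort generator with planted ground truth.

Emulates the study conditions the pipeline expects — ~12 participants
observed for 28 days with hourly task prompts from 7 AM to 11 PM — by
generating raw event streams *feature-first*: each hour slot receives
target feature values (session counts, call counts, battery drain, noise
level, acceleration spread, network shares, Wi-Fi overlap) and the raw
streams are constructed so the extractor recovers those targets exactly
(counts) or to within rounding of the construction (time-weighted shares).

Each participant carries a latent inhibitory-control state following an
hourly AR(1) process and a trait offset tied to their BIS-11 self-control
score.  The true mean SSRT of each answered prompt is log-linear in the
standardized planted features, the trait and the latent state:

    log SSRT_it = gamma0 + u_i + sum_k beta_k z_kit + sigma_c * c_it

and every answered prompt yields an 80-trial stop-signal session simulated
from an independent-race responder whose stop process is centered on that
true SSRT.  All randomness derives from one root seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scales import BIS_SELF_CONTROL_ITEMS, EMA_POLARITY, aggregate_ema
from .sensors import EventStreams, PoiTable
from .sst import (
    RaceModelParams,
    RaceResponder,
    SessionConfig,
    SSTSession,
    generate_schedule,
    run_tracking_session,
)

__all__ = [
    "CohortConfig",
    "Cohort",
    "make_cohort",
    "make_rr",
    "make_ema",
    "make_model_matrix",
    "make_rmcorr_data",
    "DEFAULT_EFFECTS",
]

# Planted log-SSRT effects per standard deviation of each feature target;
# signs follow the directions reported for the corresponding markers
# (e.g. burstiness up -> SSRT up, short sessions up -> SSRT down).
DEFAULT_EFFECTS: dict[str, float] = {
    "phone.burstiness": +0.06,
    "phone.n_short": -0.06,
    "call.n_incoming": +0.06,
    "battery.discharge_rate": +0.06,
    "noise.db_mean": -0.06,
    "activity.accel_sd": -0.06,
    "network.pct_mobile": -0.06,
    "wifi.jaccard": -0.06,
}

STUDY_T0 = 1704067200  # 2024-01-01 00:00 UTC, a Monday
FIRST_SLOT = 5         # raw streams start two hours before the first prompt
LAST_SLOT = 23


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and effect parameters of the synthetic cohort."""

    n_participants: int = 12
    days: int = 28
    prompt_hours: tuple[int, ...] = tuple(range(7, 24))
    compliance: float = 0.38
    ar_rho: float = 0.6
    state_scale: float = 0.08      # log-SSRT units per latent-state SD
    trait_sd: float = 0.12         # log-SSRT units per trait SD
    gamma0: float = math.log(280.0)
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    ema_coupling: float = 0.0
    race_go_mu_ms: float = 400.0
    race_go_sigma_ms: float = 50.0
    race_go_tau_ms: float = 100.0
    race_ssrt_sd_ms: float = 15.0
    race_p_go_omission: float = 0.02
    race_p_choice_error: float = 0.02
    with_hrv: bool = False
    hrv_sdnn_ms: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar_rho < 1.0:
            raise ValueError("ar_rho must lie in [0, 1)")
        if not 0.0 < self.compliance <= 1.0:
            raise ValueError("compliance must lie in (0, 1]")


@dataclass
class Cohort:
    """Generated streams, prompts, sessions, questionnaires and ground truth."""

    streams: dict
    prompts: pd.DataFrame
    sessions: dict
    ema: pd.DataFrame
    bis: pd.DataFrame
    ground_truth: pd.DataFrame
    poi: PoiTable
    rr: dict
    config: CohortConfig


def _slot_targets(z: np.ndarray) -> dict:
    """Map i.i.d. standard-normal draws to realizable physical targets.

    Returns both the physical target and the realized standardized value
    actually encoded in the stream (discreteness and clipping make the
    realized value the ground truth, not the raw draw).
    """
    t: dict[str, float] = {}
    n_sessions = int(np.clip(round(6 + 2 * z[0]), 1, 12))
    t["phone.burstiness"] = n_sessions
    t["z.phone.burstiness"] = (n_sessions - 6) / 2.0
    n_short = int(np.clip(round(2 + z[1]), 0, min(n_sessions, 5)))
    t["phone.n_short"] = n_short
    t["z.phone.n_short"] = n_short - 2.0
    n_in = int(np.clip(round(1.5 + 0.7 * z[2]), 0, 4))
    t["call.n_incoming"] = n_in
    t["z.call.n_incoming"] = (n_in - 1.5) / 0.7
    rate = float(np.clip(0.002 + 0.0008 * z[3], 0.0003, 0.005))
    t["battery.discharge_rate"] = rate
    t["z.battery.discharge_rate"] = (rate - 0.002) / 0.0008
    db = float(np.clip(50 + 5 * z[4], 30, 70))
    t["noise.db_mean"] = db
    t["z.noise.db_mean"] = (db - 50) / 5.0
    accel_sd = float(np.clip(1.0 + 0.3 * z[5], 0.1, 2.5))
    t["activity.accel_sd"] = accel_sd
    t["z.activity.accel_sd"] = (accel_sd - 1.0) / 0.3
    k_mob = int(round(np.clip(0.4 + 0.15 * z[6], 0.05, 0.95) * 6))
    t["network.pct_mobile"] = 100.0 * k_mob / 6.0
    t["z.network.pct_mobile"] = (k_mob / 6.0 - 0.4) / 0.15
    j_target = float(np.clip(0.5 + 0.2 * z[7], 0.0, 1.0))
    m_keep = int(round(12 * j_target / (1 + j_target)))  # |A|=|B|=6
    j_real = m_keep / (12 - m_keep)
    t["wifi.jaccard"] = j_real
    t["wifi.m_keep"] = m_keep
    t["z.wifi.jaccard"] = (j_real - 0.5) / 0.2
    return t


_ACCEL_PATTERN = np.tile([-1.0, 1.0], 6)
_ACCEL_PATTERN = _ACCEL_PATTERN / _ACCEL_PATTERN.std(ddof=1)
_NOISE_OFFSETS = np.array([-5.0, -3.0, -1.0, 1.0, 3.0, 5.0])


def _participant_streams(
    pid: str, lat0: float, cfg: CohortConfig, rng: np.random.Generator
) -> tuple[EventStreams, dict]:
    """Build all raw streams for one participant; return streams and the
    per-slot target dictionary keyed by slot start time."""
    screen, calls, battery, activity, gps, wifi, noise, network = (
        [] for _ in range(8)
    )
    slot_targets: dict[float, dict] = {}
    ssid_counter = 0
    prev_ssids: list[str] = []
    for d in range(cfg.days):
        for s in range(FIRST_SLOT, LAST_SLOT + 1):
            t0 = float(STUDY_T0 + d * 86400 + s * 3600)
            tg = _slot_targets(rng.standard_normal(8))
            slot_targets[t0] = tg

            n = int(tg["phone.burstiness"])
            n_short = int(tg["phone.n_short"])
            spacing = 3600.0 / n
            for i in range(n):
                start = t0 + i * spacing + 5.0
                dur = 10.0 if i < n_short else 120.0
                screen.append((start, "unlock"))
                screen.append((start + dur, "lock"))

            for j in range(int(tg["call.n_incoming"])):
                calls.append(("in", t0 + 50.0 + j * 400.0, 60.0))
            if (d + s) % 3 == 0:
                calls.append(("out", t0 + 250.0, 90.0))

            rate = tg["battery.discharge_rate"]
            battery.append((t0 + 1.0, 85.0, False))
            battery.append((t0 + 3599.0, 85.0 - rate * 3598.0, False))

            accel_sd = tg["activity.accel_sd"]
            for k in range(12):
                label = "stationary" if k < 8 else "walking"
                activity.append(
                    (t0 + 10.0 + 300.0 * k, label,
                     1.5 + accel_sd * _ACCEL_PATTERN[k], 50.0, 30.0)
                )

            db = tg["noise.db_mean"]
            for k in range(6):
                off = _NOISE_OFFSETS[k]
                noise.append(
                    (t0 + 20.0 + 600.0 * k, 800.0 + 50.0 * off, db + off,
                     0.1 + 0.01 * off)
                )

            k_mob = int(round(tg["network.pct_mobile"] / 100.0 * 6))
            for k in range(6):
                state = "mobile" if k < k_mob else "wifi"
                network.append((t0 + 600.0 * k, state))

            m_keep = int(tg["wifi.m_keep"])
            keep = prev_ssids[:m_keep]
            fresh = []
            for _ in range(6 - len(keep)):
                fresh.append(f"{pid}-ap{ssid_counter}")
                ssid_counter += 1
            cur_ssids = keep + fresh
            wifi.append((t0 + 30.0, ";".join(cur_ssids)))
            prev_ssids = cur_ssids

            at_home = s >= 20 or s <= 8
            gps.append((t0 + 40.0, lat0 + (0.0 if at_home else 0.002), -75.0))

    streams = EventStreams(
        screen=pd.DataFrame(screen, columns=["ts", "event"]),
        calls=pd.DataFrame(calls, columns=["direction", "start", "duration"]).sort_values(
            "start", kind="stable"
        ).reset_index(drop=True),
        battery=pd.DataFrame(battery, columns=["ts", "level", "charging"]),
        activity=pd.DataFrame(
            activity, columns=["ts", "label", "accel", "steps", "distance"]
        ),
        gps=pd.DataFrame(gps, columns=["ts", "lat", "lon"]),
        wifi=pd.DataFrame(
            [(t, tuple(s.split(";"))) for t, s in wifi], columns=["ts", "ssids"]
        ),
        noise=pd.DataFrame(noise, columns=["ts", "frequency", "db", "rms"]),
        network=pd.DataFrame(network, columns=["ts", "state"]),
    )
    return streams, slot_targets


def _bis_items(eta: float, rng: np.random.Generator) -> tuple[list[int], float]:
    """30 BIS item scores whose self-control subset sums to ~15 + 3*eta.

    Returns the items and the realized standardized trait value."""
    target = int(np.clip(round(15 + 3 * eta), 6, 24))
    subset = [1, 1, 1, 1, 1, 1]
    remaining = target - 6
    i = 0
    while remaining > 0:
        add = min(3, remaining)
        subset[i] += add
        remaining -= add
        i += 1
    items = list(rng.integers(1, 5, size=30))
    for idx, val in zip(BIS_SELF_CONTROL_ITEMS, subset):
        items[idx - 1] = val
    return [int(v) for v in items], (target - 15) / 3.0


def make_ema(
    state: float,
    coupling: float,
    rng: np.random.Generator,
    bias: float = 0.0,
) -> list[int]:
    """Six momentary item scores driven by the latent control state.

    A higher latent state means lower momentary inhibitory control, so with
    positive coupling the underlying self-reported control level falls as
    the state rises; negatively worded items move the opposite way.
    """
    level = 3.0 + bias - coupling * state
    scores = []
    for positive in EMA_POLARITY:
        base = level if positive else 6.0 - level
        scores.append(int(np.clip(round(base + 0.8 * rng.standard_normal()), 0, 6)))
    return scores


def make_rr(
    duration_s: float,
    target_sdnn_ms: float,
    band: str = "hf",
    seed: int | np.random.Generator = 0,
    start_s: float = 0.0,
    n_ectopic: int = 0,
):
    """RR-interval series with a single-tone modulation of known band.

    Base 1000 ms intervals modulated sinusoidally at 0.1 Hz (``band='lf'``)
    or 0.3 Hz (``'hf'``), amplitude scaled so the interval SD matches
    ``target_sdnn_ms``; optional ectopic beats (interval doubled) support
    cleaning tests.  Returns an :class:`~stopsense.hrv.RRSeries`.
    """
    from .hrv import RRSeries

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freq = {"lf": 0.1, "hf": 0.3}[band]
    amp = target_sdnn_ms * math.sqrt(2.0)
    t = start_s
    times, rrs = [], []
    while t - start_s < duration_s:
        rr = 1000.0 + amp * math.sin(2 * math.pi * freq * (t - start_s))
        if target_sdnn_ms > 0:
            rr += 0.5 * rng.standard_normal()
        t += rr / 1000.0
        times.append(t)
        rrs.append(rr)
    times = np.array(times)
    rrs = np.array(rrs)
    if n_ectopic:
        idx = rng.choice(np.arange(5, len(rrs) - 5), size=n_ectopic, replace=False)
        rrs[idx] = 2200.0
    return RRSeries(times, rrs)


def make_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort with planted ground truth."""
    cfg = config or CohortConfig()
    root = np.random.SeedSequence(cfg.seed)
    part_seeds = root.spawn(cfg.n_participants)

    poi_rows = []
    streams: dict[str, EventStreams] = {}
    sessions: dict[tuple[str, float], SSTSession] = {}
    rr: dict[tuple[str, float], object] = {}
    prompt_rows, ema_rows, bis_rows, gt_rows = [], [], [], []
    session_cfg = SessionConfig()
    n_hours = max(cfg.days * 24, 1)

    for p in range(cfg.n_participants):
        pid = f"p{p:02d}"
        rng = np.random.default_rng(part_seeds[p])
        lat0 = 40.0 + p * 0.01
        poi_rows.append((lat0, -75.0, "Residence"))
        poi_rows.append((lat0 + 0.002, -75.0, "College & University"))

        st, slot_targets = _participant_streams(pid, lat0, cfg, rng)
        streams[pid] = st

        bis_items, eta_real = _bis_items(rng.standard_normal(), rng)
        u = cfg.trait_sd * eta_real
        bis_rows.append(
            {"participant_id": pid,
             **{f"item{i+1}": v for i, v in enumerate(bis_items)}}
        )
        ema_bias = 0.5 * rng.standard_normal()

        # hourly AR(1) latent state, stationary unit variance
        innov = rng.standard_normal(n_hours) * math.sqrt(1 - cfg.ar_rho**2)
        c = np.empty(n_hours)
        c[0] = rng.standard_normal()
        for h in range(1, n_hours):
            c[h] = cfg.ar_rho * c[h - 1] + innov[h]

        for d in range(cfg.days):
            for h in cfg.prompt_hours:
                if rng.random() >= cfg.compliance:
                    continue
                t = float(STUDY_T0 + d * 86400 + h * 3600)
                state = c[d * 24 + h]
                tg = slot_targets[t - 3600.0]  # the hour before the prompt
                log_mu = cfg.gamma0 + u + cfg.state_scale * state
                for feat, beta in cfg.effects.items():
                    log_mu += beta * tg[f"z.{feat}"]
                true_ssrt = float(np.clip(math.exp(log_mu), 60.0, 1400.0))

                params = RaceModelParams(
                    go_mu_ms=cfg.race_go_mu_ms,
                    go_sigma_ms=cfg.race_go_sigma_ms,
                    go_tau_ms=cfg.race_go_tau_ms,
                    ssrt_mean_ms=true_ssrt,
                    ssrt_sd_ms=cfg.race_ssrt_sd_ms,
                    p_go_omission=cfg.race_p_go_omission,
                    p_choice_error=cfg.race_p_choice_error,
                )
                schedule = generate_schedule(session_cfg, rng)
                responder = RaceResponder(params, rng, session_cfg.trial_interval_ms)
                sessions[(pid, t)] = run_tracking_session(
                    schedule, responder, session_cfg
                )

                ema_scores = make_ema(state, cfg.ema_coupling, rng, ema_bias)
                ema_rows.append(
                    {"participant_id": pid, "end_s": t,
                     **{f"item{i+1}": v for i, v in enumerate(ema_scores)},
                     "ema_score": aggregate_ema(ema_scores)}
                )
                if cfg.with_hrv:
                    rr[(pid, t)] = make_rr(
                        3600.0, cfg.hrv_sdnn_ms,
                        band="hf" if state < 0 else "lf",
                        seed=rng, start_s=t - 3600.0,
                    )

                prompt_rows.append({"participant_id": pid, "end_s": t})
                gt_rows.append(
                    {"participant_id": pid, "end_s": t, "state": float(state),
                     "trait": u, "true_ssrt_ms": true_ssrt,
                     **{f"planted.{k}": v for k, v in tg.items()
                        if not k.startswith("z.") and k != "wifi.m_keep"},
                     **{k: v for k, v in tg.items() if k.startswith("z.")}}
                )

    poi = PoiTable(venues=pd.DataFrame(poi_rows, columns=["lat", "lon", "category"]))
    return Cohort(
        streams=streams,
        prompts=pd.DataFrame(prompt_rows, columns=["participant_id", "end_s"]),
        sessions=sessions,
        ema=pd.DataFrame(ema_rows),
        bis=pd.DataFrame(bis_rows),
        ground_truth=pd.DataFrame(gt_rows),
        poi=poi,
        rr=rr,
        config=cfg,
    )


def make_model_matrix(
    n_subjects: int = 12,
    n_per_subject: int = 90,
    effects: dict | None = None,
    n_null_features: int = 5,
    subject_sd: float = 0.10,
    ar_rho: float = 0.6,
    state_scale: float = 0.08,
    gamma0: float = math.log(280.0),
    gamma_shape: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Model-matrix-level cohort for calibration studies.

    Skips stream construction and task simulation: standardized features
    are drawn i.i.d. per window and the SSRT outcome is Gamma-distributed
    around the same log-linear mean structure used by the full generator.
    Intended for type-I-error and parameter-recovery simulations where many
    replicates are needed.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    feat_names = list(effects) + [f"null{i}" for i in range(n_null_features)]
    rows = []
    for s in range(n_subjects):
        u = subject_sd * rng.standard_normal()
        c = rng.standard_normal()
        for i in range(n_per_subject):
            c = ar_rho * c + math.sqrt(1 - ar_rho**2) * rng.standard_normal()
            z = rng.standard_normal(len(feat_names))
            log_mu = gamma0 + u + state_scale * c
            for j, name in enumerate(effects):
                log_mu += effects[name] * z[j]
            mu = math.exp(log_mu)
            y = rng.gamma(gamma_shape, mu / gamma_shape)
            rows.append(
                {"participant_id": f"s{s:02d}", "end_s": float(i),
                 **dict(zip(feat_names, z)), "ssrt_ms": y}
            )
    return pd.DataFrame(rows)


def make_rmcorr_data(
    n_subjects: int = 12,
    n_per_subject: int = 90,
    r: float = 0.8,
    offset_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired repeated measures with a planted common within-subject
    correlation ``r`` and arbitrary per-subject offsets in both variables."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        ox, oy = offset_sd * rng.standard_normal(2)
        x = rng.standard_normal(n_per_subject)
        y = r * x + math.sqrt(1 - r**2) * rng.standard_normal(n_per_subject)
        for xi, yi in zip(x, y):
            rows.append({"subject": f"s{s:02d}", "x": xi + ox, "y": yi + oy})
    return pd.DataFrame(rows)
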