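"""Stop-signal task engine.

Generates randomized stop-signal task (SST) sessions, runs the
one-up-one-down stop-signal-delay (SSD) tracking staircase against a
responder, estimates the central stop-signal reaction time (SSRT) with the
integration method of the independent horse-race model, and applies
session-level outlier-exclusion rules.

The horse-race model assumes that on every stop trial a go process and a
stop process race independently; an overt response is produced iff the go
process finishes before ``SSD + stop finishing time``.  The tracking
staircase raises the SSD by one step after each successful stop and lowers
it after each stop failure, so the stop-failure rate converges to 0.5 and
the integration method can read the SSRT off the go-RT distribution:

    SSRT = RT_50 - SSD(p(respond|signal) = 0.5)

where RT_50 is the median of the correct go RTs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "SessionConfig",
    "TrialRecord",
    "SSTSession",
    "RaceModelParams",
    "RaceResponder",
    "SSRTEstimate",
    "generate_schedule",
    "run_tracking_session",
    "simulate_race_trial",
    "estimate_ssrt_integration",
    "apply_exclusion",
    "simulate_tracked_stop_trials",
]

GO = "go"
STOP = "stop"


class ConfigurationError(ValueError):
    """Raised when a session configuration is internally inconsistent."""


class ProtocolError(RuntimeError):
    """Raised when a responder violates the trial protocol."""


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one SST session.

    Defaults mirror a mobile implementation with 80 trials per session,
    75% go trials, 1500 ms trial interval and a 25 ms tracking step
    starting from a 250 ms SSD.
    """

    n_trials: int = 80
    go_fraction: float = 0.75
    trial_interval_ms: float = 1500.0
    blank_ms: float = 500.0
    fixation_ms: float = 500.0
    ssd_init_ms: float = 250.0
    ssd_step_ms: float = 25.0
    ssd_min_ms: float = 0.0
    ssd_max_ms: float = 1250.0

    def __post_init__(self) -> None:
        n_go = self.n_trials * self.go_fraction
        if abs(n_go - round(n_go)) > 1e-9:
            raise ConfigurationError(
                f"n_trials*go_fraction = {n_go} is not an integer"
            )
        if self.ssd_min_ms < 0:
            raise ConfigurationError("ssd_min_ms must be >= 0")
        if self.ssd_max_ms > self.trial_interval_ms - self.ssd_step_ms:
            raise ConfigurationError(
                "ssd_max_ms must leave room inside the trial interval"
            )

    @property
    def n_go(self) -> int:
        return round(self.n_trials * self.go_fraction)

    @property
    def n_stop(self) -> int:
        return self.n_trials - self.n_go


@dataclass
class TrialRecord:
    """One logged trial: kind, stimulus, SSD (stop trials), response and RT."""

    index: int
    kind: str
    go_stimulus: str
    ssd_ms: float | None = None
    response: str = "none"
    rt_ms: float | None = None

    @property
    def stop_success(self) -> bool | None:
        if self.kind != STOP:
            return None
        return self.response == "none"


@dataclass
class SSTSession:
    """A full trial log of one SST session."""

    trials: list[TrialRecord]
    config: SessionConfig = field(default_factory=SessionConfig)

    @property
    def stop_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.kind == STOP]

    @property
    def go_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.kind == GO]

    def correct_go_rts(self) -> np.ndarray:
        """RTs of go trials answered on the correct side."""
        side = {"L": "left", "R": "right"}
        return np.array(
            [
                t.rt_ms
                for t in self.go_trials
                if t.rt_ms is not None and t.response == side[t.go_stimulus]
            ],
            dtype=float,
        )

    def to_jsonl(self) -> str:
        lines = []
        for t in self.trials:
            lines.append(
                json.dumps(
                    {
                        "index": t.index,
                        "kind": t.kind,
                        "stimulus": t.go_stimulus,
                        "ssd_ms": t.ssd_ms,
                        "response": t.response,
                        "rt_ms": t.rt_ms,
                    }
                )
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str, config: SessionConfig | None = None) -> "SSTSession":
        trials = []
        for line in text.strip().splitlines():
            d = json.loads(line)
            trials.append(
                TrialRecord(
                    index=d["index"],
                    kind=d["kind"],
                    go_stimulus=d["stimulus"],
                    ssd_ms=d.get("ssd_ms"),
                    response=d.get("response", "none"),
                    rt_ms=d.get("rt_ms"),
                )
            )
        return cls(trials=trials, config=config or SessionConfig())


@dataclass(frozen=True)
class RaceModelParams:
    """Independent-race responder parameters.

    The go process finishes after an ex-Gaussian time
    ``Normal(go_mu_ms, go_sigma_ms) + Exponential(go_tau_ms)``; the stop
    process finishes ``Normal(ssrt_mean_ms, ssrt_sd_ms)`` after the stop
    signal.  ``ssrt_mean_ms`` is the true SSRT that recovery tests target.
    """

    go_mu_ms: float = 400.0
    go_sigma_ms: float = 50.0
    go_tau_ms: float = 100.0
    ssrt_mean_ms: float = 250.0
    ssrt_sd_ms: float = 0.0
    p_go_omission: float = 0.0
    p_choice_error: float = 0.0

    def __post_init__(self) -> None:
        if min(self.go_mu_ms, self.go_sigma_ms, self.go_tau_ms) <= 0:
            raise ValueError("ex-Gaussian parameters must be > 0")
        if self.ssrt_mean_ms <= 0 or self.ssrt_sd_ms < 0:
            raise ValueError("stop-process parameters out of range")
        for p in (self.p_go_omission, self.p_choice_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def simulate_race_trial(
    params: RaceModelParams,
    kind: str,
    ssd_ms: float | None,
    rng: np.random.Generator,
    trial_interval_ms: float = 1500.0,
) -> tuple[str, float | None]:
    """Simulate one trial under the independent race model.

    Returns ``(response, rt_ms)`` where response is ``"correct"``,
    ``"error"`` or ``"none"`` relative to the go stimulus; the caller maps
    correct/error onto left/right.  Go finishes later than the trial
    interval count as omissions.
    """
    t_go = (
        params.go_mu_ms
        + params.go_sigma_ms * rng.standard_normal()
        + rng.exponential(params.go_tau_ms)
    )
    omitted = rng.random() < params.p_go_omission or t_go > trial_interval_ms
    if kind == STOP:
        t_stop = params.ssrt_mean_ms + params.ssrt_sd_ms * rng.standard_normal()
        if t_go >= ssd_ms + t_stop:
            return "none", None
    if omitted:
        return "none", None
    response = "error" if rng.random() < params.p_choice_error else "correct"
    return response, float(max(t_go, 1e-9))


class RaceResponder:
    """Adapter turning :func:`simulate_race_trial` into a session responder.

    Maps correct/error onto the left/right side implied by the go stimulus.
    """

    def __init__(
        self,
        params: RaceModelParams,
        rng: np.random.Generator,
        trial_interval_ms: float = 1500.0,
    ) -> None:
        self.params = params
        self.rng = rng
        self.trial_interval_ms = trial_interval_ms

    def __call__(
        self, kind: str, go_stimulus: str, ssd_ms: float | None
    ) -> tuple[str, float | None]:
        outcome, rt = simulate_race_trial(
            self.params, kind, ssd_ms, self.rng, self.trial_interval_ms
        )
        if outcome == "none":
            return "none", None
        correct = "left" if go_stimulus == "L" else "right"
        wrong = "right" if go_stimulus == "L" else "left"
        return (correct if outcome == "correct" else wrong), rt


def generate_schedule(
    config: SessionConfig, seed: int | np.random.Generator
) -> list[tuple[str, str]]:
    """Seeded random trial order with go stimuli drawn L/R equiprobably."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kinds = np.array([GO] * config.n_go + [STOP] * config.n_stop)
    kinds = kinds[rng.permutation(config.n_trials)]
    stimuli = rng.choice(["L", "R"], size=config.n_trials)
    return [(str(k), str(s)) for k, s in zip(kinds, stimuli)]


def run_tracking_session(
    schedule: Sequence[tuple[str, str]],
    responder: Callable[[str, str, float | None], tuple[str, float | None]],
    config: SessionConfig | None = None,
) -> SSTSession:
    """Run the one-up-one-down SSD staircase over a trial schedule.

    The first stop trial presents ``ssd_init_ms``; after each successful
    stop the next stop trial's SSD rises by one step, after each failure it
    falls by one step, clamped to ``[ssd_min_ms, ssd_max_ms]``.
    """
    config = config or SessionConfig()
    ssd = config.ssd_init_ms
    trials: list[TrialRecord] = []
    for i, (kind, stim) in enumerate(schedule):
        trial_ssd = ssd if kind == STOP else None
        response, rt = responder(kind, stim, trial_ssd)
        if rt is not None and rt > config.trial_interval_ms:
            raise ProtocolError(
                f"responder returned rt {rt} ms > trial interval"
            )
        trials.append(
            TrialRecord(
                index=i,
                kind=kind,
                go_stimulus=stim,
                ssd_ms=trial_ssd,
                response=response,
                rt_ms=rt,
            )
        )
        if kind == STOP:
            step = config.ssd_step_ms if response == "none" else -config.ssd_step_ms
            ssd = min(max(ssd + step, config.ssd_min_ms), config.ssd_max_ms)
    return SSTSession(trials=trials, config=config)


@dataclass
class SSRTEstimate:
    """Integration-method SSRT estimate for one session."""

    ssrt_ms: float | None
    ssd_at_half_ms: float | None
    rt50_ms: float | None
    p_respond_overall: float
    per_ssd: list[tuple[float, float, float]]
    n_stop: int
    n_go: int
    estimable: bool
    exclusion_reason: str = "none"


def estimate_ssrt_integration(session: SSTSession) -> SSRTEstimate:
    """Estimate the central SSRT of one session by the integration method.

    For each distinct SSD the stop-failure rate p(respond|signal) and the
    p*100-th percentile of the correct-go RT distribution are computed;
    linear interpolation across SSD-sorted (SSD, p) pairs locates the SSD
    where p crosses 0.5, and SSRT = RT_50 - SSD(0.5).  Sessions whose
    (SSD, p) curve never crosses 0.5 are flagged not estimable.
    """
    stops = session.stop_trials
    go_rts = session.correct_go_rts()
    n_stop = len(stops)
    n_go = len(session.go_trials)
    n_fail = sum(1 for t in stops if t.response != "none")
    p_overall = n_fail / n_stop if n_stop else float("nan")

    if n_stop == 0 or go_rts.size == 0:
        return SSRTEstimate(
            ssrt_ms=None,
            ssd_at_half_ms=None,
            rt50_ms=None,
            p_respond_overall=p_overall,
            per_ssd=[],
            n_stop=n_stop,
            n_go=n_go,
            estimable=False,
            exclusion_reason="not_estimable",
        )

    by_ssd: dict[float, list[bool]] = {}
    for t in stops:
        by_ssd.setdefault(t.ssd_ms, []).append(t.response != "none")
    ssds = sorted(by_ssd)
    per_ssd = []
    for s in ssds:
        fails = by_ssd[s]
        p = sum(fails) / len(fails)
        nth_rt = float(np.percentile(go_rts, p * 100.0)) if p > 0 else float(go_rts.min())
        per_ssd.append((float(s), float(p), nth_rt))

    rt50 = float(np.percentile(go_rts, 50.0))
    ssd_half = _first_half_crossing(per_ssd)
    if ssd_half is None:
        return SSRTEstimate(
            ssrt_ms=None,
            ssd_at_half_ms=None,
            rt50_ms=rt50,
            p_respond_overall=p_overall,
            per_ssd=per_ssd,
            n_stop=n_stop,
            n_go=n_go,
            estimable=False,
            exclusion_reason="not_estimable",
        )
    return SSRTEstimate(
        ssrt_ms=rt50 - ssd_half,
        ssd_at_half_ms=ssd_half,
        rt50_ms=rt50,
        p_respond_overall=p_overall,
        per_ssd=per_ssd,
        n_stop=n_stop,
        n_go=n_go,
        estimable=True,
    )


def _first_half_crossing(
    per_ssd: Sequence[tuple[float, float, float]]
) -> float | None:
    """First SSD (ascending) where the failure-rate curve meets 0.5."""
    for ssd, p, _ in per_ssd:
        if p == 0.5:
            return ssd
    for (s0, p0, _), (s1, p1, _) in zip(per_ssd, per_ssd[1:]):
        if (p0 - 0.5) * (p1 - 0.5) < 0:
            return s0 + (0.5 - p0) * (s1 - s0) / (p1 - p0)
    return None


def apply_exclusion(
    estimates: Iterable[SSRTEstimate],
    p_low: float = 0.25,
    p_high: float = 0.75,
    ssrt_low_ms: float = 50.0,
    ssrt_high_ms: float = 1500.0,
) -> tuple[list[SSRTEstimate], list[tuple[SSRTEstimate, str]]]:
    """Drop sessions failing any outlier rule (union reading).

    A session is excluded if its overall stop-failure rate falls outside
    [0.25, 0.75], its SSRT falls outside [50, 1500] ms, or the estimate is
    not estimable.  The boundary values themselves are retained.
    """
    kept: list[SSRTEstimate] = []
    dropped: list[tuple[SSRTEstimate, str]] = []
    for est in estimates:
        if not est.estimable:
            reason = "not_estimable"
        elif est.p_respond_overall < p_low or est.p_respond_overall > p_high:
            reason = "p_out_of_range"
        elif est.ssrt_ms < ssrt_low_ms or est.ssrt_ms > ssrt_high_ms:
            reason = "ssrt_out_of_range"
        else:
            est.exclusion_reason = "none"
            kept.append(est)
            continue
        est.exclusion_reason = reason
        dropped.append((est, reason))
    return kept, dropped


def simulate_tracked_stop_trials(
    params: RaceModelParams,
    n_stop_trials: int,
    seed: int | np.random.Generator,
    config: SessionConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Run a long staircase of consecutive stop trials.

    Returns the overall stop-failure proportion and the SSD sequence;
    convergence of the proportion to 0.5 is the behavioral signature of
    the one-up-one-down tracking rule.
    """
    config = config or SessionConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ssd = config.ssd_init_ms
    ssds = np.empty(n_stop_trials)
    failures = 0
    for i in range(n_stop_trials):
        ssds[i] = ssd
        response, _ = simulate_race_trial(
            params, STOP, ssd, rng, config.trial_interval_ms
        )
        if response == "none":
            ssd += config.ssd_step_ms
        else:
            failures += 1
            ssd -= config.ssd_step_ms
        ssd = min(max(ssd, config.ssd_min_ms), config.ssd_max_ms)
    return failures / n_stop_trials, ssds
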