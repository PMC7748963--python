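"""Heart-rate-variability features from RR-interval series.

Pipeline per analysis window: check that the window holds at least five
minutes of continuous beat-to-beat recording, remove ectopic/outlier beats
and replace them by cubic interpolation (yielding NN intervals), then
compute time-domain (HR mean/SD, SDNN, SDANN, RMSSD, SDSD, triangular
index) and frequency-domain features (relative low-frequency 0.04-0.15 Hz
and high-frequency 0.15-0.4 Hz power by Welch/FFT, Lomb-Scargle, and an
autoregressive spectrum).

Sample (n-1) standard deviations are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from statsmodels.regression.linear_model import burg

__all__ = [
    "RRSeries",
    "QualityError",
    "check_coverage",
    "clean_rr",
    "time_domain",
    "sdann",
    "freq_domain",
    "hrv_features",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TOTAL_BAND = (0.04, 0.40)
RR_BOUNDS_MS = (300.0, 2000.0)
ECTOPIC_REL_DIFF = 0.20
MAX_BEAT_GAP_S = 3.0
MIN_COVERAGE_S = 300.0
TRI_BIN_MS = 7.8125
RESAMPLE_HZ = 4.0
WELCH_SEGMENT_S = 120.0
AR_ORDER = 16


class QualityError(ValueError):
    """Raised when too many beats fail the cleaning criteria."""


@dataclass
class RRSeries:
    """Beat timestamps (s) and RR intervals (ms); rr[i] ends at beat_times[i]."""

    beat_times_s: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.beat_times_s.shape != self.rr_ms.shape:
            raise ValueError("beat_times_s and rr_ms must have equal length")
        if len(self.rr_ms) and (self.rr_ms <= 0).any():
            raise ValueError("RR intervals must be positive")

    @classmethod
    def from_rr(cls, rr_ms, start_s: float = 0.0) -> "RRSeries":
        rr = np.asarray(rr_ms, dtype=float)
        return cls(start_s + np.cumsum(rr) / 1000.0, rr)

    def slice(self, start_s: float, end_s: float) -> "RRSeries":
        m = (self.beat_times_s >= start_s) & (self.beat_times_s < end_s)
        return RRSeries(self.beat_times_s[m], self.rr_ms[m])


def check_coverage(rr: RRSeries) -> bool:
    """True iff some run with inter-beat gaps <= 3 s spans >= 5 minutes."""
    t = rr.beat_times_s
    if len(t) < 2:
        return False
    breaks = np.flatnonzero(np.diff(t) > MAX_BEAT_GAP_S)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(t) - 1]))
    spans = t[ends] - t[starts]
    return bool((spans >= MIN_COVERAGE_S).any())


def clean_rr(
    rr: RRSeries,
    bounds_ms: tuple[float, float] = RR_BOUNDS_MS,
    rel_diff: float = ECTOPIC_REL_DIFF,
    max_flagged: float = 0.20,
) -> RRSeries:
    """Flag outlier/ectopic beats and replace them by cubic interpolation.

    A beat is flagged if its interval leaves ``bounds_ms`` or differs from
    the previous accepted interval by more than ``rel_diff``.  Flagged
    intervals are replaced by a cubic spline over beat index fitted to the
    accepted beats; output length equals input length.  If more than
    ``max_flagged`` of beats are flagged the window is rejected.
    """
    x = rr.rr_ms.copy()
    n = len(x)
    if n == 0:
        return RRSeries(rr.beat_times_s.copy(), x)
    ok = np.ones(n, dtype=bool)
    prev = None
    for i in range(n):
        bad = not (bounds_ms[0] <= x[i] <= bounds_ms[1])
        if not bad and prev is not None:
            bad = abs(x[i] - prev) > rel_diff * prev
        if bad:
            ok[i] = False
        else:
            prev = x[i]
    n_flagged = int((~ok).sum())
    if n_flagged > max_flagged * n:
        raise QualityError(
            f"{n_flagged}/{n} beats flagged (> {max_flagged:.0%}); window rejected"
        )
    if n_flagged and ok.sum() >= 2:
        idx = np.arange(n)
        spline = CubicSpline(idx[ok], x[ok])
        x[~ok] = spline(idx[~ok])
    return RRSeries(rr.beat_times_s.copy(), x)


def time_domain(nn: RRSeries) -> dict:
    """HR statistics, SDNN, RMSSD, SDSD and the geometric triangular index."""
    x = nn.rr_ms
    out = {
        "hrv.mean_hr": np.nan,
        "hrv.sd_hr": np.nan,
        "hrv.sdnn": np.nan,
        "hrv.rmssd": np.nan,
        "hrv.sdsd": np.nan,
        "hrv.tri_index": np.nan,
    }
    if len(x) == 0:
        return out
    hr = 60000.0 / x
    out["hrv.mean_hr"] = float(hr.mean())
    if len(x) > 1:
        out["hrv.sd_hr"] = float(hr.std(ddof=1))
        out["hrv.sdnn"] = float(x.std(ddof=1))
        d = np.diff(x)
        out["hrv.rmssd"] = float(np.sqrt(np.mean(d**2)))
        out["hrv.sdsd"] = float(d.std(ddof=1)) if len(d) > 1 else np.nan
    # histogram with 1/128 s bins aligned at zero
    edges = np.arange(0.0, x.max() + 2 * TRI_BIN_MS, TRI_BIN_MS)
    counts, _ = np.histogram(x, bins=edges)
    if counts.max() > 0:
        out["hrv.tri_index"] = float(len(x) / counts.max())
    return out


def sdann(nn: RRSeries, segment_s: float = 300.0) -> float:
    """SD of per-5-minute mean NN; NaN when fewer than 2 complete segments."""
    t = nn.beat_times_s
    if len(t) < 2:
        return float("nan")
    t0 = t[0]
    span = t[-1] - t0
    n_seg = int(span // segment_s)
    means = []
    for k in range(n_seg):
        m = (t >= t0 + k * segment_s) & (t < t0 + (k + 1) * segment_s)
        if m.any():
            means.append(nn.rr_ms[m].mean())
    if len(means) < 2:
        return float("nan")
    return float(np.std(means, ddof=1))


def _resample_tachogram(nn: RRSeries, fs: float = RESAMPLE_HZ):
    t = nn.beat_times_s
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    x = CubicSpline(t, nn.rr_ms)(grid)
    return grid, x - x.mean()


def _band_power(f: np.ndarray, pxx: np.ndarray, band: tuple[float, float]) -> float:
    m = (f >= band[0]) & (f <= band[1])
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(pxx[m], f[m]))


def freq_domain(nn: RRSeries, method: str = "fft") -> tuple[float, float]:
    """Relative LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) spectral power.

    ``fft``: cubic resampling to an even 4 Hz tachogram, mean detrending,
    Welch spectrum (120 s segments, 50% overlap).  ``lomb``: Lomb-Scargle
    periodogram evaluated on the unevenly sampled beats directly.  ``ar``:
    Burg autoregressive spectrum of order 16 on the resampled tachogram.
    Powers are normalized by the total 0.04-0.4 Hz power.
    """
    if len(nn.rr_ms) < 4 or np.ptp(nn.rr_ms) == 0:
        return float("nan"), float("nan")
    if method == "fft":
        _, x = _resample_tachogram(nn)
        nperseg = min(len(x), int(WELCH_SEGMENT_S * RESAMPLE_HZ))
        f, pxx = signal.welch(x, fs=RESAMPLE_HZ, nperseg=nperseg)
    elif method == "lomb":
        t = nn.beat_times_s
        x = nn.rr_ms - nn.rr_ms.mean()
        f = np.linspace(0.005, 0.5, 1000)
        pxx = signal.lombscargle(t, x, 2 * np.pi * f, normalize=False)
    elif method == "ar":
        _, x = _resample_tachogram(nn)
        if len(x) <= AR_ORDER + 1:
            return float("nan"), float("nan")
        rho, sigma2 = burg(x, order=AR_ORDER)
        f = np.linspace(0.001, RESAMPLE_HZ / 2, 2048)
        z = np.exp(-2j * np.pi * np.outer(f, np.arange(1, AR_ORDER + 1)) / RESAMPLE_HZ)
        denom = np.abs(1.0 - z @ rho) ** 2
        pxx = sigma2 / (RESAMPLE_HZ * denom)
    else:
        raise ValueError(f"unknown method {method!r}")
    total = _band_power(f, pxx, TOTAL_BAND)
    if total <= 0:
        return float("nan"), float("nan")
    return (
        _band_power(f, pxx, LF_BAND) / total,
        _band_power(f, pxx, HF_BAND) / total,
    )


def hrv_features(window_rr: RRSeries) -> dict:
    """All HRV features for one window's RR series; NaNs on quality failure.

    The coverage gate (>= 5 min continuous recording) and the cleaning
    quality gate are applied first; a window failing either yields NaNs.
    """
    names = [
        "hrv.mean_hr", "hrv.sd_hr", "hrv.sdnn", "hrv.sdann", "hrv.rmssd",
        "hrv.sdsd", "hrv.tri_index",
        "hrv.rel_lf_fft", "hrv.rel_hf_fft",
        "hrv.rel_lf_lomb", "hrv.rel_hf_lomb",
        "hrv.rel_lf_ar", "hrv.rel_hf_ar",
    ]
    out = {k: np.nan for k in names}
    if not check_coverage(window_rr):
        return out
    try:
        nn = clean_rr(window_rr)
    except QualityError:
        return out
    out.update(time_domain(nn))
    out["hrv.sdann"] = sdann(nn)
    for method in ("fft", "lomb", "ar"):
        lf, hf = freq_domain(nn, method)
        out[f"hrv.rel_lf_{method}"] = lf
        out[f"hrv.rel_hf_{method}"] = hf
    return out
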