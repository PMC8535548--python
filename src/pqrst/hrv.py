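"""Heart-rate-variability metrics and per-beat interval trends.

Time-domain metrics summarize the RR (NN) interval series directly: mean
and spread of RR and instantaneous heart rate, the counts NN50/pNN50 of
adjacent-interval jumps above 50 ms, RMSSD, and the geometric histogram
measures HTI (count over modal bin height) and TINN (baseline width of
the least-squares triangular fit to the RR histogram).

Frequency-domain metrics integrate the power spectral density of the RR
tachogram over the conventional bands VLF [0, 0.04), LF [0.04, 0.15) and
HF [0.15, 0.40) Hz.  The default estimator linearly resamples the
tachogram onto a uniform grid (4 Hz), removes the mean, and applies a
Welch averaged periodogram; a Lomb-Scargle mode works on the unevenly
sampled intervals directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger("pqrst")

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass(frozen=True)
class RRSeries:
    """RR intervals (s) and the time stamp (s) at each interval's end."""

    intervals: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.intervals <= 0):
            raise ValueError("all RR intervals must be positive")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @classmethod
    def from_r_indices(cls, r_indices, fs: float,
                       rr_filter: bool = False,
                       rr_range: tuple = (0.2, 3.0)) -> "RRSeries":
        r = np.asarray(sorted(r_indices), dtype=float)
        if r.size < 2:
            raise ValueError("need at least two R-peaks")
        rr = np.diff(r) / fs
        ts = r[1:] / fs
        if rr_filter:
            keep = (rr >= rr_range[0]) & (rr <= rr_range[1])
            rr, ts = rr[keep], ts[keep]
        return cls(intervals=rr, timestamps=ts)


@dataclass(frozen=True)
class HRVTimeMetrics:
    rr_mean_s: float
    rr_std_s: float
    hr_mean_bpm: float
    hr_std_bpm: float
    nn50: int
    pnn50_pct: float
    rmssd_ms: float
    hti: float
    tinn_ms: float


@dataclass(frozen=True)
class HRVFreqMetrics:
    vlf_power_ms2: float
    lf_power_ms2: float
    hf_power_ms2: float
    vlf_pct: float
    lf_pct: float
    hf_pct: float
    lf_norm: float
    hf_norm: float
    lf_hf_ratio: float


def _triangular_fit(counts: np.ndarray) -> tuple[int, int]:
    """(n, p) bin bounds of the least-squares triangular interpolation.

    The triangle is zero outside [n, p], rises linearly to the histogram
    peak bin and falls linearly after it; n and p minimize the squared
    deviation from the histogram.
    """
    m = int(np.argmax(counts))
    y = counts.astype(float)
    k = y.size

    def sse_rise(n: int) -> float:
        # bins 0..m: zero before n, linear from (n, 0) to (m, y[m])
        err = float(np.sum(y[:n] ** 2))
        span = m - n
        if span > 0:
            line = y[m] * (np.arange(n, m) - n) / span
            err += float(np.sum((y[n:m] - line) ** 2))
        return err

    def sse_fall(p: int) -> float:
        err = float(np.sum(y[p + 1:] ** 2))
        span = p - m
        if span > 0:
            line = y[m] * (p - np.arange(m + 1, p + 1)) / span
            err += float(np.sum((y[m + 1:p + 1] - line) ** 2))
        return err

    n_best = min(range(0, m + 1), key=sse_rise)
    p_best = min(range(m, k), key=sse_fall)
    return n_best, p_best


def time_domain_metrics(rr: RRSeries, bin_width_s: float = 1.0 / 128.0) -> HRVTimeMetrics:
    """The nine time-domain HRV measures of an RR series.

    NN50 counts strict |delta| > 50 ms; pNN50 normalizes by the number of
    adjacent pairs; the HR spread uses the per-interval instantaneous rate
    60/RR.  HTI and TINN use an RR histogram with the conventional 1/128 s
    bins; a single-bin (constant) series has HTI = 1 and TINN = 0.
    """
    x = np.asarray(rr.intervals, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two RR intervals")
    d = np.diff(x)
    hr = 60.0 / x
    nn50 = int(np.sum(np.abs(d) > 0.050))
    first = math.floor(x.min() / bin_width_s)
    last = math.floor(x.max() / bin_width_s)
    edges = (np.arange(first, last + 2)) * bin_width_s
    counts, _ = np.histogram(x, bins=edges)
    hti = x.size / counts.max()
    if np.count_nonzero(counts) <= 1:
        tinn_ms = 0.0
    else:
        n, p = _triangular_fit(counts)
        tinn_ms = (p - n) * bin_width_s * 1000.0
    return HRVTimeMetrics(
        rr_mean_s=float(x.mean()),
        rr_std_s=float(x.std()),
        hr_mean_bpm=float(60.0 / x.mean()),
        hr_std_bpm=float(hr.std()),
        nn50=nn50,
        pnn50_pct=100.0 * nn50 / (x.size - 1),
        rmssd_ms=float(np.sqrt(np.mean(d ** 2))) * 1000.0,
        hti=float(hti),
        tinn_ms=float(tinn_ms),
    )


def _band_power(f: np.ndarray, pxx: np.ndarray, band: tuple[float, float]) -> float:
    mask = (f >= band[0]) & (f < band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(pxx[mask], f[mask]))


def frequency_domain_metrics(rr: RRSeries, resample_hz: float = 4.0,
                             welch_sec: float = 120.0,
                             method: str = "welch") -> HRVFreqMetrics:
    """Band powers (ms^2) and normalized quantities of the RR tachogram.

    "welch": linear interpolation onto a uniform ``resample_hz`` grid,
    mean removal, Welch PSD with segments of ``welch_sec`` where the
    record allows.  "lomb": Lomb-Scargle periodogram of the unevenly
    sampled intervals (no resampling).  Normalized units follow the
    standard definitions: LF norm = 100*LF/(total - VLF), percentages are
    of the total power up to the Nyquist (or highest evaluated) frequency.
    A series shorter than ~60 s is allowed with a warning.
    """
    t = rr.timestamps
    x_ms = rr.intervals * 1000.0
    span = t[-1] - t[0]
    if span < 60.0:
        logger.warning("RR series spans only %.1f s; spectral estimates are unreliable", span)

    if method == "welch":
        grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
        tach = np.interp(grid, t, x_ms)
        tach = tach - tach.mean()
        nperseg = min(tach.size, int(welch_sec * resample_hz))
        f, pxx = sps.welch(tach, fs=resample_hz, nperseg=max(nperseg, 8))
    elif method == "lomb":
        f = np.linspace(1e-4, 0.5, 2000)
        pxx = sps.lombscargle(t, x_ms - x_ms.mean(), 2 * np.pi * f, normalize=False)
        pxx = pxx / np.pi  # angular-frequency periodogram -> per-Hz density
    else:
        raise ValueError(f"unknown method {method!r}")

    total = float(np.trapezoid(pxx, f))
    vlf = _band_power(f, pxx, VLF_BAND)
    lf = _band_power(f, pxx, LF_BAND)
    hf = _band_power(f, pxx, HF_BAND)

    def pct(p: float) -> float:
        return 100.0 * p / total if total > 0 else float("nan")

    denom = total - vlf
    lf_norm = 100.0 * lf / denom if denom > 0 else float("nan")
    hf_norm = 100.0 * hf / denom if denom > 0 else float("nan")
    ratio = lf / hf if hf > 0 else float("nan")
    return HRVFreqMetrics(vlf_power_ms2=vlf, lf_power_ms2=lf, hf_power_ms2=hf,
                          vlf_pct=pct(vlf), lf_pct=pct(lf), hf_pct=pct(hf),
                          lf_norm=lf_norm, hf_norm=hf_norm, lf_hf_ratio=ratio)


def interval_trends(beats, fs: float) -> pd.DataFrame:
    """Per-beat ST-segment, PR-interval and QT-interval durations (s).

    ST = S-offset to T-onset, PR = P-onset to Q-onset, QT = Q-onset to
    T-offset.  Beats whose P-wave was mapped yield PR values computed from
    the mapped indices (near zero when the whole P maps to the Q-onset).
    """
    rows = []
    for i, b in enumerate(beats):
        f = b.fiducials if hasattr(b, "fiducials") else b
        rows.append({
            "beat": i,
            "time_s": f.r_peak / fs,
            "st_s": (f.t_onset - f.s_offset) / fs,
            "pr_s": (f.q_onset - f.p_onset) / fs,
            "qt_s": (f.t_offset - f.q_onset) / fs,
        })
    return pd.DataFrame(rows, columns=["beat", "time_s", "st_s", "pr_s", "qt_s"])
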