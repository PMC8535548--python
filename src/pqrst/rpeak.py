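"""R-peak and fragmented-R detection from the background-subtracted residual.

The normalized window I minus the bilateral-filter background B leaves a
residual D that is large only over the QRS interval.  A short moving sum
(the "enhanced" residual E) widens and stabilizes the QRS signature; runs
of at least L consecutive samples with |E| above half its window maximum
are candidate-R intervals, and the signed extremum of I inside each run is
the R-peak.  The polarity factor gamma is +1 for upright R-waves and -1
for inverted ones (e.g. premature ventricular contractions).

Fragmented (notched) R-waves carry additional secondary peaks on either
flank of the main R.  A point is an additional R-peak when the gamma-
oriented slope sign reverses there and the rebound amplitude -- a 10-term
sum of two-step sample differences moving away from the main peak --
exceeds the threshold Thf.  The search recurses outward so double-notch
patterns (fR-L2/fR-R2) are found as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import DetectorConfig, SamplingContext

logger = logging.getLogger("pqrst")


@dataclass(frozen=True)
class NormalizedWindow:
    """A window of dimensionless samples plus its mean (Imean)."""

    samples: np.ndarray
    mean_value: float


@dataclass(frozen=True)
class ResidualSignals:
    """Residual D, enhanced residual E and binary candidate mask CR."""

    residual: np.ndarray
    enhanced: np.ndarray
    candidate_mask: np.ndarray


@dataclass
class RPeakInfo:
    """One detected R-peak with polarity and fragment annotations."""

    index: int
    gamma: int
    is_flat: bool = False
    additional_right: list[int] = field(default_factory=list)
    additional_left: list[int] = field(default_factory=list)

    @property
    def leftmost(self) -> int:
        """Leftmost accepted R (RL of a left-fragmented wave, else R)."""
        return self.additional_left[-1] if self.additional_left else self.index

    @property
    def rightmost(self) -> int:
        return self.additional_right[-1] if self.additional_right else self.index


def normalize_window(raw_samples, mode: str = "minmax") -> NormalizedWindow:
    """Normalize a raw window to dimensionless units.

    "minmax" maps the window affinely onto [0, 1]; "literal_eq1" divides
    (S - Smin) by Smax instead, which only lands in [0, 1] for non-negative
    records.  Constant windows are degenerate and rejected.
    """
    s = np.asarray(raw_samples, dtype=float)
    if s.size == 0:
        raise ValueError("cannot normalize an empty window")
    smin, smax = float(s.min()), float(s.max())
    if smax == smin:
        raise ValueError("degenerate (constant) window cannot be normalized")
    if mode == "minmax":
        i = (s - smin) / (smax - smin)
    elif mode == "literal_eq1":
        if smax == 0:
            raise ValueError("literal_eq1 normalization undefined for Smax=0")
        i = (s - smin) / smax
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return NormalizedWindow(samples=i, mean_value=float(i.mean()))


def enhance_residual(residual, n: int) -> np.ndarray:
    """Moving sum of the residual over [x-n, x+n], zero-padded at the edges."""
    if n < 0:
        raise ValueError("half-width must be >= 0")
    d = np.asarray(residual, dtype=float)
    if n == 0:
        return d.copy()
    return np.convolve(d, np.ones(2 * n + 1), mode="same")


def candidate_r_intervals(enhanced, threshold: float, min_run: int = 8) -> list[tuple[int, int]]:
    """Maximal runs (start, stop) of E > threshold with length >= min_run.

    Returned spans are half-open and in increasing order; the empty list is
    a legal result.
    """
    e = np.asarray(enhanced, dtype=float)
    if e.size == 0:
        raise ValueError("enhanced residual must be non-empty")
    above = e > threshold
    runs: list[tuple[int, int]] = []
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    for a, b in zip(run_starts, run_stops):
        if b - a >= min_run:
            runs.append((int(a), int(b)))
    return runs


def locate_r_peak(window: NormalizedWindow, run: tuple[int, int]) -> tuple[int, int, bool]:
    """R-peak index, polarity gamma and flat-top flag for one candidate run.

    gamma=+1 (argmax) when the run's maximum rises at least as far above
    Imean as its minimum falls below; otherwise gamma=-1 (argmin).  Ties at
    the extremum (a flat top) resolve to the floor of their mean position.
    """
    a, b = run
    if not (0 <= a < b <= window.samples.size):
        raise ValueError(f"run {run} outside window of length {window.samples.size}")
    seg = window.samples[a:b]
    imean = window.mean_value
    if (seg.max() - imean) >= (imean - seg.min()):
        gamma, extremum = 1, seg.max()
    else:
        gamma, extremum = -1, seg.min()
    ties = np.flatnonzero(seg == extremum)
    index = a + int(np.floor(ties.mean()))
    return index, gamma, bool(ties.size > 1)


def _rebound_sum(i: np.ndarray, c: int, gamma: int, direction: int, terms: int) -> float:
    """Gamma-oriented rebound amplitude: sum of two-step differences moving
    away from the main R.  Terms running off the window end the sum early."""
    total = 0.0
    n = i.size
    truncated = False
    for m in range(1, terms + 1):
        near = c + direction * (m - 1)
        far = c + direction * (m + 1)
        if not (0 <= near < n and 0 <= far < n):
            truncated = True
            break
        total += gamma * (i[near] - i[far])
    if truncated:
        logger.debug("rebound sum at %d truncated by window edge", c)
    return total


def detect_additional_r(window: NormalizedWindow, r: RPeakInfo, side: str,
                        config: DetectorConfig, fs: float) -> list[int]:
    """Additional (fragmented) R-peaks on one flank of a detected R.

    Scans outward from R+-1; each scan extends alpha_f = round(fs*QRS/2)
    samples beyond the most recently accepted peak.  A sample is accepted
    when the gamma-oriented slope sign crosses from <=0 to >=0 (a secondary
    gamma-extremum) and its rebound amplitude exceeds Thf.  Accepted
    indices are returned in scan order (moving away from R).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    direction = 1 if side == "right" else -1
    i = window.samples
    n = i.size
    alpha_f = int(round(0.5 * fs * config.qrs_sec))
    d1 = np.empty(n)
    d1[:-1] = i[:-1] - i[1:]          # I'(t) = I(t) - I(t+1)
    d1[-1] = 0.0
    gamma = r.gamma

    found: list[int] = []
    anchor = r.index
    c = r.index + direction
    # a flat-top plateau is part of the R apex, not a fragment
    while 0 < c < n - 1 and i[c] == i[r.index]:
        c += direction
    limit = anchor + direction * alpha_f
    while True:
        if direction > 0 and (c > limit or c >= n - 1):
            break
        if direction < 0 and (c < limit or c < 1):
            break
        slope_ok = (gamma * np.sign(d1[c - 1]) <= 0) and (gamma * np.sign(d1[c]) >= 0)
        if slope_ok and c not in (anchor,):
            reb = _rebound_sum(i, c, gamma, direction, config.fragment_sum_terms)
            if reb > config.th_f:
                found.append(int(c))
                anchor = c
                limit = anchor + direction * alpha_f
                if not (0 <= limit < n):
                    logger.debug("fragment search range truncated at window edge")
        c += direction
    return found


def detect_r_peaks(window: NormalizedWindow, background: np.ndarray,
                   config: DetectorConfig, fs: float) -> tuple[list[RPeakInfo], ResidualSignals]:
    """All R-peaks of one normalized window, with fragment annotations.

    The candidate rule runs on |E| with Thc = max|E|/2 so inverted-QRS
    beats (negative residual) are reachable; runs whose peaks collide
    within the refractory period keep the larger deviation from Imean.
    """
    ctx = SamplingContext(fs)
    i = window.samples
    d = i - background
    n_enh = ctx.scale_count(config.enhance_half_width_ref)
    e = enhance_residual(d, n_enh)
    abs_e = np.abs(e)
    thc = config.thc_ratio * float(abs_e.max())
    min_run = ctx.scale_count(config.min_run_ref)
    runs = candidate_r_intervals(abs_e, thc, min_run=min_run)

    mask = np.zeros(i.size, dtype=np.int8)
    peaks: list[RPeakInfo] = []
    for run in runs:
        mask[run[0]:run[1]] = 1
        idx, gamma, flat = locate_r_peak(window, run)
        peaks.append(RPeakInfo(index=idx, gamma=gamma, is_flat=flat))

    # refractory merge: keep the larger |I - Imean| of colliding peaks
    refr = ctx.samples(config.refractory_sec)
    merged: list[RPeakInfo] = []
    for p in sorted(peaks, key=lambda p: p.index):
        if merged and p.index - merged[-1].index < refr:
            prev = merged[-1]
            if abs(i[p.index] - window.mean_value) > abs(i[prev.index] - window.mean_value):
                merged[-1] = p
        else:
            merged.append(p)

    for p in merged:
        p.additional_right = detect_additional_r(window, p, "right", config, fs)
        p.additional_left = detect_additional_r(window, p, "left", config, fs)
    return merged, ResidualSignals(residual=d, enhanced=e, candidate_mask=mask)
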