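"""Sliding-window segmentation and seamless record-level stitching.

The detector processes a record in fixed-length overlapping windows (2000
samples with a 1600-sample step at the 360 Hz reference rate) so that all
window-level statistics (Smin/Smax, Imean, Emax) stay local, as a
streaming implementation requires.  Beats whose fiducial search ranges fit
entirely inside a window are "perfect"; beats too close to a window edge
are provisional and are finalized by a later window that covers them.
Stitching merges per-window beat lists into one record-level stream:
beats reported by several windows are matched within a tolerance and a
single representative is kept (a complete beat from the earliest window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import DetectorConfig, SamplingContext, DEFAULT_CONFIG
from .rpeak import RPeakInfo, normalize_window, detect_r_peaks
from .bilateral import FilterParams, bilateral_filter
from .delineation import BeatFiducials, SearchRanges, delineate_beat

logger = logging.getLogger("pqrst")


@dataclass(frozen=True)
class WindowPlan:
    """Sliding-window geometry: length, step and resulting start offsets."""

    window_len: int = 2000
    step: int = 1600

    def __post_init__(self) -> None:
        if not (0 < self.step < self.window_len):
            raise ValueError("need 0 < step < window_len (overlap must exist)")

    @classmethod
    def for_fs(cls, fs: float, config: DetectorConfig = DEFAULT_CONFIG) -> "WindowPlan":
        ctx = SamplingContext(fs)
        return cls(window_len=ctx.scale_count(config.window_len_ref),
                   step=ctx.scale_count(config.window_step_ref))


def segment_windows(record_length: int, plan: WindowPlan) -> list[tuple[int, int]]:
    """Half-open window spans covering the record.

    Spans are [k*step, k*step + window_len) clipped to the record end; a
    new window is added only while the previous one has not yet reached
    the end of the record, so consecutive spans overlap by
    window_len - step samples and the last window may be short.
    """
    if record_length < 1:
        raise ValueError("record_length must be >= 1")
    spans = [(0, min(plan.window_len, record_length))]
    k = 1
    while (k - 1) * plan.step + plan.window_len < record_length:
        start = k * plan.step
        spans.append((start, min(start + plan.window_len, record_length)))
        k += 1
    return spans


@dataclass
class DetectedBeat:
    """One stitched beat: absolute-index fiducials plus R-peak metadata."""

    fiducials: BeatFiducials
    r: RPeakInfo
    window_start: int = 0
    perfect: bool = True

    @property
    def r_index(self) -> int:
        return self.fiducials.r_peak


def _shift_rpeak(r: RPeakInfo, offset: int) -> RPeakInfo:
    return RPeakInfo(index=r.index + offset, gamma=r.gamma, is_flat=r.is_flat,
                     additional_right=[i + offset for i in r.additional_right],
                     additional_left=[i + offset for i in r.additional_left])


def _margins(ranges: SearchRanges) -> tuple[int, int]:
    # a beat is "perfect" when its full delineation support fits inside the
    # window: Q + Q-onset + P spans to the left, S + S-offset + T to the right
    left = ranges.alpha_q + ranges.alpha_ql + ranges.alpha_p + ranges.alpha_f
    right = ranges.alpha_s + ranges.alpha_sr + ranges.alpha_t + ranges.alpha_f
    return left, right


def process_window(raw: np.ndarray, fs: float,
                   config: DetectorConfig = DEFAULT_CONFIG) -> list[DetectedBeat]:
    """Run the full per-window pipeline; indices are window-relative."""
    try:
        window = normalize_window(raw, mode=config.normalize_mode)
    except ValueError:
        return []    # constant (flat-line) window carries no beats
    params = FilterParams(half_width=config.filter_half_width,
                          sigma_d_max=config.sigma_d_max,
                          sigma_r_max=config.sigma_r_max,
                          sigma_min=config.sigma_min,
                          sigma2_max=config.sigma2_max,
                          clamp=config.clamp_sigmas)
    background = bilateral_filter(window.samples, params)
    peaks, _ = detect_r_peaks(window, background, config, fs)

    beats: list[DetectedBeat] = []
    prev_t_offset = None
    for j, r in enumerate(peaks):
        next_r = peaks[j + 1].index if j + 1 < len(peaks) else None
        fid = delineate_beat(window, background, r, config, fs,
                             prev_t_offset=prev_t_offset, next_r=next_r)
        prev_t_offset = fid.t_offset
        beats.append(DetectedBeat(fiducials=fid, r=r))
    return beats


def stitch_annotations(per_window_beats: list[list[DetectedBeat]],
                       tolerance_ms: float, fs: float) -> list[DetectedBeat]:
    """Merge per-window beat lists (absolute indices) into one stream.

    Beats from different windows whose R-peaks agree within the tolerance
    are one beat; the kept representative is a perfect (fully delineated)
    beat from the earliest window reporting one, falling back to the
    earliest provisional detection.  Output R-peaks are strictly
    increasing with no two closer than the tolerance.  Stitching an
    already-stitched list is the identity.
    """
    tol = int(round(tolerance_ms / 1000.0 * fs))
    candidates: list[tuple[int, int, DetectedBeat]] = []
    for w, beats in enumerate(per_window_beats):
        for b in beats:
            candidates.append((b.r_index, w, b))
    candidates.sort(key=lambda t: (t[0], t[1]))

    out: list[DetectedBeat] = []
    group: list[tuple[int, int, DetectedBeat]] = []

    def flush() -> None:
        if not group:
            return
        perfect = [g for g in group if g[2].perfect]
        pick = perfect[0] if perfect else group[0]
        if len({g[1] for g in group}) < len(group):
            spread = max(g[0] for g in group) - min(g[0] for g in group)
            if spread > tol:
                logger.warning("seam beats differ by %d samples (> tolerance)", spread)
        out.append(pick[2])
        group.clear()

    for cand in candidates:
        if group and cand[0] - group[0][0] >= tol:
            flush()
        group.append(cand)
    flush()
    return out


def detect_record(signal, fs: float,
                  config: DetectorConfig = DEFAULT_CONFIG) -> list[DetectedBeat]:
    """Detect and delineate every beat of a single-lead record.

    The record is cut into overlapping sliding windows, each window is
    processed independently (normalization, background prediction, R-peak
    detection, delineation) and the per-window annotations are stitched
    into one seamless stream of absolute-index beats.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D sequence")
    ctx = SamplingContext(fs)
    plan = WindowPlan.for_fs(fs, config)
    ranges = SearchRanges.from_context(ctx, config)
    m_left, m_right = _margins(ranges)

    per_window: list[list[DetectedBeat]] = []
    spans = segment_windows(x.size, plan)
    for (a, b) in spans:
        beats = process_window(x[a:b], fs, config)
        shifted: list[DetectedBeat] = []
        for beat in beats:
            fid = beat.fiducials.shift(a)
            r = _shift_rpeak(beat.r, a)
            # provisional edge beats survive stitching only when no other
            # window re-detects them (record-boundary beats)
            interior = (beat.r.index >= m_left) and (beat.r.index < (b - a) - m_right)
            shifted.append(DetectedBeat(fiducials=fid, r=r, window_start=a,
                                        perfect=interior))
        per_window.append(shifted)
    return stitch_annotations(per_window, config.stitch_tolerance_ms, fs)


def r_peak_indices(beats: list[DetectedBeat]) -> np.ndarray:
    return np.array([b.r_index for b in beats], dtype=int)
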