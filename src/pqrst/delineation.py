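"""Q/S and P/T fiducial delineation around detected R-peaks.

Q and S (and their onset/offset shoulders) are found on the normalized
signal I by slope-sign scans anchored at the R-peak: the Q- and S-points
are the first gamma-oriented troughs scanning away from R, and the Q-onset
/ S-offset are the first relaxed shoulders (slope levels off or reverses)
scanning beyond them.

P- and T-wave fiducials are found on the bilateral-filter background B,
where QRS energy is suppressed but the low, gentle P/T lobes survive.  A
symmetric "point filter" slides through the search range: a candidate is a
wave peak when at least a fraction rho of its left-wing slopes rise toward
it and its right-wing slopes fall away (orientation flipped for inverted
waves, omega=-1).  The v-recursion skips v samples nearest the candidate
so plateaued or deformed apexes still fire; the smallest firing v is
recorded.  Onsets and offsets use short asymmetric filters (2 outer / 4
inner wing points, all required) that fire at the toe where the flank
slope meets the flat baseline.  When both an upright and an inverted
candidate wave exist, the inverted one is chosen only if it is both wider
and subtends a larger triangle area.  Fiducials that cannot be detected
are mapped to their anchors so every beat ends up with all 11 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .config import DetectorConfig, SamplingContext
from .rpeak import NormalizedWindow, RPeakInfo

FIDUCIAL_NAMES = (
    "p_onset", "p_peak", "p_offset",
    "q_onset", "q_peak", "r_peak",
    "s_peak", "s_offset",
    "t_onset", "t_peak", "t_offset",
)


@dataclass(frozen=True)
class SearchRanges:
    """Per-record search spans (sample counts) for all fiducial scans."""

    alpha_q: int
    alpha_qm: int
    alpha_ql: int
    alpha_s: int
    alpha_sr: int
    alpha_f: int
    alpha_p: int
    alpha_t: int

    @classmethod
    def from_context(cls, ctx: SamplingContext, config: DetectorConfig) -> "SearchRanges":
        qrs = ctx.samples(config.qrs_sec)
        half_qrs = int(round(ctx.fs * config.qrs_sec / 2))
        return cls(
            alpha_q=half_qrs + config.alpha_qm,
            alpha_qm=config.alpha_qm,
            alpha_ql=qrs,
            alpha_s=half_qrs + config.alpha_qm,
            alpha_sr=qrs,
            alpha_f=half_qrs,
            alpha_p=ctx.samples(config.pr_sec),
            alpha_t=ctx.samples(config.qt_sec - config.qrs_sec),
        )


@dataclass(frozen=True)
class PointFilterParams:
    """Symmetric point-filter constants for one wave (P or T).

    The wings at deformation v are wing_ref - v samples each side; rho is
    the fraction of wing conditions that must hold.  Onset/offset bounds
    use the asymmetric outer/inner wings with all conditions required.
    """

    wing_ref: int
    rho: float
    v_max: int
    outer_wing: int = 2
    inner_wing: int = 4

    @classmethod
    def for_wave(cls, wave: str, config: DetectorConfig) -> "PointFilterParams":
        if wave == "P":
            return cls(config.p_wing_ref, config.rho_p, config.v_p_max,
                       config.bound_outer_wing, config.bound_inner_wing)
        if wave == "T":
            return cls(config.t_wing_ref, config.rho_t, config.v_t_max,
                       config.bound_outer_wing, config.bound_inner_wing)
        raise ValueError(f"wave must be 'P' or 'T', got {wave!r}")


@dataclass
class BeatFiducials:
    """The 11 fiducials of one beat with polarity and mapping metadata."""

    p_onset: int
    p_peak: int
    p_offset: int
    q_onset: int
    q_peak: int
    r_peak: int
    s_peak: int
    s_offset: int
    t_onset: int
    t_peak: int
    t_offset: int
    p_omega: int = 1
    t_omega: int = 1
    v_p_true: int = 0
    v_t_true: int = 0
    mapped: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in FIDUCIAL_NAMES}

    def ordered(self) -> bool:
        vals = [getattr(self, name) for name in FIDUCIAL_NAMES]
        return all(a <= b for a, b in zip(vals, vals[1:]))

    def shift(self, offset: int) -> "BeatFiducials":
        kw = {name: getattr(self, name) + offset for name in FIDUCIAL_NAMES}
        return BeatFiducials(**kw, p_omega=self.p_omega, t_omega=self.t_omega,
                             v_p_true=self.v_p_true, v_t_true=self.v_t_true,
                             mapped=set(self.mapped))


class WaveCandidate(NamedTuple):
    """A detected P/T wave: peak with optional onset/offset bounds."""

    onset: Optional[int]
    peak: int
    offset: Optional[int]
    omega: int
    v_true: int


def _backward_diff(values: np.ndarray) -> np.ndarray:
    """I'(t) = I(t) - I(t+1); last entry padded with 0."""
    d = np.empty(values.size)
    d[:-1] = values[:-1] - values[1:]
    d[-1] = 0.0
    return d


# ---------------------------------------------------------------------------
# Q / S fiducials on the normalized signal
# ---------------------------------------------------------------------------

def _scan_trough(i: np.ndarray, gamma: int, start: int, stop: int, step: int) -> Optional[int]:
    # gamma-oriented strict local extremum opposite the R polarity:
    # gamma*I'(c-1) > 0 (falls into c) and gamma*I'(c) < 0 (rises after).
    d1 = _backward_diff(i)
    n = i.size
    for c in range(start, stop + step, step):
        if c < 1 or c > n - 2:
            continue
        if gamma * d1[c - 1] > 0 and gamma * d1[c] < 0:
            return c
    return None


def detect_q(window: NormalizedWindow, r: RPeakInfo,
             ranges: SearchRanges) -> tuple[int, bool]:
    """Q-point: first gamma-trough scanning left from R (or RL) - 1.

    Falls back to the leftmost scan position, flagged mapped.
    """
    start = r.leftmost - 1
    stop = max(r.leftmost - ranges.alpha_q, 0)
    c = _scan_trough(window.samples, r.gamma, start, stop, -1)
    if c is None:
        return stop, True
    return c, False


def detect_s(window: NormalizedWindow, r: RPeakInfo,
             ranges: SearchRanges) -> tuple[int, bool]:
    """S-point: first gamma-trough scanning right from R (or RR) + 1."""
    n = window.samples.size
    start = r.rightmost + 1
    stop = min(r.rightmost + ranges.alpha_s, n - 1)
    c = _scan_trough(window.samples, r.gamma, start, stop, 1)
    if c is None:
        return stop, True
    return c, False


def detect_q_onset(window: NormalizedWindow, q_index: int, gamma: int,
                   ranges: SearchRanges) -> tuple[int, bool]:
    """Q-onset: first relaxed gamma-shoulder scanning left from Q-1.

    The shoulder condition is a relaxed local maximum (for gamma=+1):
    gamma*I'(c-1) <= 0 and gamma*I'(c+r) >= 0 for r=0 or 1, so flat
    plateaus qualify (sign 0 passes both inequalities).
    """
    i = window.samples
    d1 = _backward_diff(i)
    n = i.size
    start = q_index - 1
    stop = max(q_index - ranges.alpha_ql, 0)
    for c in range(start, stop - 1, -1):
        if c < 1 or c > n - 2:
            continue
        look = gamma * d1[c] >= 0 or (c + 1 <= n - 2 and gamma * d1[c + 1] >= 0)
        if gamma * d1[c - 1] <= 0 and look:
            return c, False
    return stop, True


def detect_s_offset(window: NormalizedWindow, s_index: int, gamma: int,
                    ranges: SearchRanges) -> tuple[int, bool]:
    """S-offset: mirror of the Q-onset scan, rightward from S+1."""
    i = window.samples
    d1 = _backward_diff(i)
    n = i.size
    start = s_index + 1
    stop = min(s_index + ranges.alpha_sr, n - 1)
    for c in range(start, stop + 1):
        if c < 1 or c > n - 2:
            continue
        look = gamma * d1[c - 1] <= 0 or (c - 2 >= 0 and gamma * d1[c - 2] <= 0)
        if gamma * d1[c] >= 0 and look:
            return c, False
    return stop, True


# ---------------------------------------------------------------------------
# P / T waves on the predicted background
# ---------------------------------------------------------------------------

def detect_wave_peak(background: np.ndarray, scan_range: tuple[int, int],
                     wave: str, params: PointFilterParams,
                     omega: Optional[int] = None) -> Optional[tuple[int, int, int]]:
    """P- or T-point via the symmetric point filter; None when nothing fires.

    ``scan_range`` is (start, stop) inclusive with the scan moving from
    start toward stop (start > stop scans leftward, as for the P-wave).
    For each deformation v = 0..v_max (then each omega if unrestricted),
    a candidate c is accepted when at least rho*(l+r) of the wing slopes
    satisfy omega*sign B'(c-l) <= 0 (l = v+1..v+wing) and
    omega*sign B'(c+r-1) >= 0 (r = v+1..v+wing), and the wing pattern is
    non-degenerate (an actual rise and fall exist, so flat stretches never
    fire).  Returns (index, omega, v_true) with v_true the smallest firing
    deformation.
    """
    b = np.asarray(background, dtype=float)
    start, stop = scan_range
    step = 1 if stop >= start else -1
    cands = np.arange(start, stop + step, step)
    if cands.size == 0:
        return None
    sign_d = np.sign(_backward_diff(b))
    n = b.size
    omegas = (omega,) if omega is not None else (1, -1)

    for v in range(params.v_max + 1):
        wing = params.wing_ref - v
        if wing < 1:
            break
        offs = np.arange(v + 1, v + wing + 1)
        valid = (cands - offs[-1] >= 0) & (cands + offs[-1] - 1 <= n - 2)
        if not valid.any():
            continue
        c = cands[valid]
        left = sign_d[c[:, None] - offs[None, :]]
        right = sign_d[c[:, None] + offs[None, :] - 1]
        hits: list[tuple[int, int, int]] = []   # (scan position, omega, index)
        for om in omegas:
            ls = om * left
            rs = om * right
            count = (ls <= 0).sum(axis=1) + (rs >= 0).sum(axis=1)
            ok = count >= params.rho * (2 * wing) - 1e-9
            ok &= (ls < 0).any(axis=1) & (rs > 0).any(axis=1)
            firing = np.flatnonzero(ok)
            if firing.size:
                # rho < 1 lets the filter fire a few samples before the
                # apex; the peak is the omega-extremum of B over the
                # contiguous accepted run (floor-mean centers plateaus)
                stop_at = firing[0]
                while stop_at + 1 < ok.size and ok[stop_at + 1]:
                    stop_at += 1
                run = c[firing[0]:stop_at + 1]
                vals = om * b[run]
                ties = np.flatnonzero(vals == vals.max())
                idx = int(run[int(np.floor(ties.mean()))])
                hits.append((int(firing[0]), om, idx))
        if hits:
            hits.sort(key=lambda h: (h[0], -h[1]))  # earliest scan position; tie -> omega=+1
            _, om, idx = hits[0]
            return idx, om, v
    return None


def detect_wave_bounds(background: np.ndarray, peak_index: int, omega: int,
                       v_true: int, side: str, wave: str, anchor: int,
                       params: PointFilterParams) -> Optional[int]:
    """Onset or offset of a detected P/T wave; None when no toe qualifies.

    ``anchor`` is the Q-onset for the P-wave and the S-offset for the
    T-wave; it bounds the scan on the QRS side and, mirrored about the
    peak, on the outer side.  The asymmetric filter requires ALL wing
    slopes to satisfy the omega-trough orientation (left wings >= 0, right
    wings <= 0 for omega=+1, flat passing both), with 2 outer / 4 inner
    wing points; it fires at the toe where the flank meets the baseline.
    """
    if side not in ("onset", "offset"):
        raise ValueError("side must be 'onset' or 'offset'")
    b = np.asarray(background, dtype=float)
    n = b.size
    sign_d = np.sign(_backward_diff(b))

    if side == "onset":
        lw, rw = params.outer_wing, params.inner_wing
        start = (peak_index - 1) + v_true
        if wave == "P":
            alpha = (anchor - 1) - peak_index          # mirrored Q-onset distance
            stop = peak_index - alpha
        else:
            stop = anchor + 1
        step = -1
    else:
        lw, rw = params.inner_wing, params.outer_wing
        start = (peak_index + 1) + v_true
        if wave == "P":
            stop = anchor - 1
        else:
            alpha = (peak_index - 1) - anchor          # mirrored S-offset distance
            stop = peak_index + alpha
        step = 1

    if step * (stop - start) < 0:
        return None
    for c in range(start, stop + step, step):
        if c - lw < 0 or c + rw - 1 > n - 2:
            continue
        left_ok = all(omega * sign_d[c - l] >= 0 for l in range(1, lw + 1))
        right_ok = all(omega * sign_d[c + r - 1] <= 0 for r in range(1, rw + 1))
        if left_ok and right_ok:
            return c
    return None


def _triangle_area(background: np.ndarray, onset: int, peak: int, offset: int) -> float:
    """Absolute shoelace area of the onset/peak/offset triangle on B."""
    x1, x2, x3 = float(onset), float(peak), float(offset)
    y1, y2, y3 = background[onset], background[peak], background[offset]
    return abs(x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2)) / 2.0


def select_wave_polarity(normal: Optional[WaveCandidate],
                         inverted: Optional[WaveCandidate],
                         background: np.ndarray) -> Optional[WaveCandidate]:
    """Choose between upright and inverted wave candidates.

    The inverted candidate wins only when both candidates are complete
    (onset and offset found) and it is strictly wider AND subtends a
    strictly larger triangle area; in every other case the upright
    candidate is preferred when it exists.
    """
    if normal is None and inverted is None:
        return None
    if inverted is None:
        return normal
    if normal is None:
        return inverted

    def complete(c: WaveCandidate) -> bool:
        return c.onset is not None and c.offset is not None

    if complete(normal) and complete(inverted):
        wider = (inverted.offset - inverted.onset) > (normal.offset - normal.onset)
        larger = (_triangle_area(background, inverted.onset, inverted.peak, inverted.offset)
                  > _triangle_area(background, normal.onset, normal.peak, normal.offset))
        if wider and larger:
            return inverted
    if complete(inverted) and not complete(normal):
        return inverted
    return normal


def _detect_wave(background: np.ndarray, scan_range: tuple[int, int], wave: str,
                 anchor: int, params: PointFilterParams) -> Optional[WaveCandidate]:
    """Full P- or T-wave search: both polarities, bounds, Eq.-21 selection."""
    cands: dict[int, Optional[WaveCandidate]] = {1: None, -1: None}
    for om in (1, -1):
        hit = detect_wave_peak(background, scan_range, wave, params, omega=om)
        if hit is None:
            continue
        idx, _, v_true = hit
        onset = detect_wave_bounds(background, idx, om, v_true, "onset", wave, anchor, params)
        offset = detect_wave_bounds(background, idx, om, v_true, "offset", wave, anchor, params)
        cands[om] = WaveCandidate(onset, idx, offset, om, v_true)
    return select_wave_polarity(cands[1], cands[-1], background)


# ---------------------------------------------------------------------------
# Mapping of missing fiducials and per-beat orchestration
# ---------------------------------------------------------------------------

def map_missing_fps(beat: BeatFiducials) -> BeatFiducials:
    """Map undetected P/T fiducials to their anchors.

    A missing P-peak collapses all three P fiducials onto the Q-onset; a
    missing T-peak collapses the T fiducials onto the S-offset.  With the
    peak present, a missing onset maps to the peak (P) or the S-offset (T)
    and a missing offset maps to the Q-onset (P) or the peak (T).  Every
    mapped name is recorded and the ordering invariant holds afterwards.
    Missing values are encoded as -1 on entry.
    """
    b = beat
    if b.p_peak < 0:
        b.p_onset = b.p_peak = b.p_offset = b.q_onset
        b.mapped |= {"p_onset", "p_peak", "p_offset"}
    else:
        if b.p_onset < 0:
            b.p_onset = b.p_peak
            b.mapped.add("p_onset")
        if b.p_offset < 0:
            b.p_offset = b.q_onset
            b.mapped.add("p_offset")
    if b.t_peak < 0:
        b.t_onset = b.t_peak = b.t_offset = b.s_offset
        b.mapped |= {"t_onset", "t_peak", "t_offset"}
    else:
        if b.t_onset < 0:
            b.t_onset = b.s_offset
            b.mapped.add("t_onset")
        if b.t_offset < 0:
            b.t_offset = b.t_peak
            b.mapped.add("t_offset")
    # mapping can only tighten toward the anchors; enforce monotonicity
    b.p_offset = max(b.p_offset, b.p_peak)
    b.p_onset = min(b.p_onset, b.p_peak)
    b.t_onset = min(b.t_onset, b.t_peak)
    b.t_offset = max(b.t_offset, b.t_peak)
    return b


def delineate_beat(window: NormalizedWindow, background: np.ndarray, r: RPeakInfo,
                   config: DetectorConfig, fs: float,
                   prev_t_offset: Optional[int] = None,
                   next_r: Optional[int] = None) -> BeatFiducials:
    """All 11 fiducials of one beat inside a processing window.

    ``prev_t_offset`` (previous beat's T-offset) bounds the P search below;
    ``next_r`` bounds the T search above.  Indices are window-relative.
    """
    ctx = SamplingContext(fs)
    ranges = SearchRanges.from_context(ctx, config)
    n = window.samples.size
    mapped: set[str] = set()

    q, q_m = detect_q(window, r, ranges)
    if q_m:
        mapped.add("q_peak")
    q_on, qon_m = detect_q_onset(window, q, r.gamma, ranges)
    if qon_m:
        mapped.add("q_onset")
    s, s_m = detect_s(window, r, ranges)
    if s_m:
        mapped.add("s_peak")
    s_off, soff_m = detect_s_offset(window, s, r.gamma, ranges)
    if soff_m:
        mapped.add("s_offset")

    # T-wave: rightward from S-offset + 1, bounded by alpha_T and the next R
    t_lo = s_off + 1
    t_hi = min(s_off + ranges.alpha_t, n - 2)
    if next_r is not None:
        t_hi = min(t_hi, next_r - 1)
    t_cand = None
    if t_lo <= t_hi:
        t_cand = _detect_wave(background, (t_lo, t_hi), "T", s_off,
                              PointFilterParams.for_wave("T", config))

    # P-wave: leftward from Q-onset - 1, bounded by alpha_P and the previous T-offset
    p_start = q_on - 1
    p_stop = max(q_on - ranges.alpha_p, 0)
    if prev_t_offset is not None:
        p_stop = max(p_stop, prev_t_offset + 1)
    p_cand = None
    if p_start >= p_stop:
        p_cand = _detect_wave(background, (p_start, p_stop), "P", q_on,
                              PointFilterParams.for_wave("P", config))

    def unpack(c: Optional[WaveCandidate]) -> tuple[int, int, int, int, int]:
        if c is None:
            return -1, -1, -1, 1, 0
        return (c.onset if c.onset is not None else -1, c.peak,
                c.offset if c.offset is not None else -1, c.omega, c.v_true)

    p_onset, p_peak, p_offset, p_omega, v_p = unpack(p_cand)
    t_onset, t_peak, t_offset, t_omega, v_t = unpack(t_cand)

    beat = BeatFiducials(
        p_onset=p_onset, p_peak=p_peak, p_offset=p_offset,
        q_onset=q_on, q_peak=q, r_peak=r.index,
        s_peak=s, s_offset=s_off,
        t_onset=t_onset, t_peak=t_peak, t_offset=t_offset,
        p_omega=p_omega, t_omega=t_omega,
        v_p_true=v_p, v_t_true=v_t, mapped=mapped,
    )
    beat = map_missing_fps(beat)
    beat.p_onset = max(beat.p_onset, 0)
    beat.t_offset = min(beat.t_offset, n - 1)
    return beat
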