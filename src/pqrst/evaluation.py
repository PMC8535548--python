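"""Beat-matching and delineation-error statistics.

Detection quality is scored beat-by-beat against reference annotations: a
detected R-peak matches an annotated one when they differ by less than a
fixed time tolerance (50 ms by convention), each annotation matches at
most once, and the usual sensitivity / positive prediction / detection
error rate follow from the TP/FN/FP counts.  Delineation accuracy is
summarized per fiducial by the mean m and standard deviation s of the
signed timing errors, combined into RMSE = sqrt(m^2 + s^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EvalCounts:
    """TP/FN/FP beat counts; total = tp + fn by construction."""

    tp: int
    fn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class DelineationErrors:
    """Signed-error summary (ms) for one fiducial: m, s and RMSE."""

    errors_ms: tuple
    mean_ms: float
    std_ms: float
    rmse_ms: float


def match_annotations(detected, truth, fs: float,
                      tolerance_ms: float = 50.0) -> EvalCounts:
    """Greedy one-to-one nearest matching of detected vs annotated R indices.

    A pair matches iff |dt| < tolerance; pairs are claimed in order of
    increasing |dt|, so the count is symmetric under swapping the two lists
    (FN and FP swap).  Unmatched annotations are FN, unmatched detections FP.
    """
    det = np.asarray(sorted(detected), dtype=float)
    ref = np.asarray(sorted(truth), dtype=float)
    tol = tolerance_ms / 1000.0 * fs
    pairs: list[tuple[float, int, int]] = []
    for j, t in enumerate(ref):
        lo = np.searchsorted(det, t - tol)
        hi = np.searchsorted(det, t + tol)
        for i in range(lo, hi):
            dt = abs(det[i] - t)
            if dt < tol:
                pairs.append((dt, i, j))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_d: set[int] = set()
    used_r: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        tp += 1
    return EvalCounts(tp=tp, fn=ref.size - tp, fp=det.size - tp)


def detection_metrics(counts: EvalCounts) -> tuple[float, float, float]:
    """(Se %, +P %, DER %) from beat counts.

    Se = 100*TP/(TP+FN), +P = 100*TP/(TP+FP), DER = 100*(FP+FN)/(TP+FN).
    Ratios with a zero denominator are returned as NaN.
    """
    tp, fn, fp = counts.tp, counts.fn, counts.fp
    if tp + fn <= 0:
        raise ValueError("need at least one annotated beat (tp + fn > 0)")
    se = 100.0 * tp / (tp + fn)
    pp = 100.0 * tp / (tp + fp) if tp + fp > 0 else float("nan")
    der = 100.0 * (fp + fn) / (tp + fn)
    return se, pp, der


def rmse_stats(errors_ms) -> DelineationErrors:
    """m / s / RMSE summary of signed timing errors in milliseconds.

    s is the population standard deviation; RMSE = sqrt(m^2 + s^2) equals
    the root mean square of the raw errors.
    """
    e = np.asarray(errors_ms, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one error value")
    m = float(e.mean())
    s = float(e.std())
    return DelineationErrors(errors_ms=tuple(e.tolist()), mean_ms=m, std_ms=s,
                             rmse_ms=float(np.hypot(m, s)))


def fiducial_errors_ms(detected_beats, truths, name: str, fs: float,
                       tolerance_ms: float = 50.0,
                       t_onset_exclusion_sec: float = 0.0) -> list[float]:
    """Signed errors (detected - annotated, ms) for one fiducial name.

    Beats are paired by R-peak within the tolerance first.  When
    ``t_onset_exclusion_sec`` is positive and ``name`` relates to the
    T-onset, beats whose detected S-offset and annotated T-onset are
    closer than that gap are excluded (the two points are then
    indistinguishable and reference databases leave them unannotated).
    """
    det_r = [b.fiducials.r_peak for b in detected_beats]
    ref_r = [t.fiducials["r_peak"] for t in truths]
    tol = tolerance_ms / 1000.0 * fs
    errors: list[float] = []
    ref_arr = np.asarray(ref_r, dtype=float)
    for b in detected_beats:
        if ref_arr.size == 0:
            break
        j = int(np.argmin(np.abs(ref_arr - b.fiducials.r_peak)))
        if abs(ref_arr[j] - b.fiducials.r_peak) >= tol:
            continue
        tr = truths[j]
        if (t_onset_exclusion_sec > 0 and name == "t_onset"
                and (tr.fiducials["t_onset"] - b.fiducials.s_offset) / fs
                < t_onset_exclusion_sec):
            continue
        errors.append((getattr(b.fiducials, name) - tr.fiducials[name]) / fs * 1000.0)
    return errors
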