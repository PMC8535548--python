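"""Variance-adaptive one-dimensional bilateral filter.

The filter predicts the "background" of a normalized ECG window: the P- and
T-waves and flat baseline are preserved while the narrow, high-variance QRS
interval is smoothed away.  The residual (original minus background) then
isolates the QRS for R-peak detection.

The filter weight at center x for a neighbour xi is the product of a domain
(spatial) Gaussian and a range (intensity) Gaussian,

    w(xi, x) = exp(-(xi-x)^2 / 2 sigma_d^2) * exp(-(I(xi)-I(x))^2 / 2 sigma_r^2),

normalized so that flat regions are conserved exactly.  Both standard
deviations are recomputed at every center from the local variance s2 of the
window:

    sigma = log2(s2 / sigma2_max + 1) * sigma_max + sigma_min

so low-variance (P/T/baseline) regions get a nearly degenerate kernel (the
signal passes through) and high-variance (QRS) regions get a wide kernel
(the complex is suppressed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FilterParams:
    """Constants of the adaptive bilateral filter.

    half_width: N, the window spans 2N+1 samples.
    sigma2_max: variance ceiling of the normalized signal; variances above
        it are passed through the same log2 law unless ``clamp`` is set.
    """

    half_width: int = 7
    sigma_d_max: float = 10.0
    sigma_r_max: float = 1.0
    sigma_min: float = 1e-5
    sigma2_max: float = 0.1310
    clamp: bool = False

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if min(self.sigma_d_max, self.sigma_r_max, self.sigma_min) <= 0:
            raise ValueError("sigma bounds must be positive")
        if self.sigma2_max <= 0:
            raise ValueError("sigma2_max must be positive")


def local_variance(samples) -> float:
    """Population variance of a filter window.

    Raises ValueError on an empty window.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("variance of an empty window is undefined")
    return float(np.mean((arr - arr.mean()) ** 2))


def adaptive_sigmas(variance: float, params: FilterParams) -> tuple[float, float]:
    """Domain and range standard deviations for a given local variance.

    sigma = log2(variance/sigma2_max + 1) * sigma_max + sigma_min.  At zero
    variance both collapse to sigma_min (never exactly zero); at
    variance == sigma2_max the log2 term is exactly 1.
    """
    if variance < 0:
        raise ValueError(f"variance must be non-negative, got {variance}")
    v = min(variance, params.sigma2_max) if params.clamp else variance
    g = np.log2(v / params.sigma2_max + 1.0)
    return (g * params.sigma_d_max + params.sigma_min,
            g * params.sigma_r_max + params.sigma_min)


def _padded_windows(values: np.ndarray, half_width: int) -> np.ndarray:
    """(len, 2N+1) sliding windows, NaN outside the signal (edge truncation)."""
    n = half_width
    padded = np.concatenate([np.full(n, np.nan), values, np.full(n, np.nan)])
    return np.lib.stride_tricks.sliding_window_view(padded, 2 * n + 1)


def bilateral_filter(signal, params: FilterParams = FilterParams()) -> np.ndarray:
    """Predicted background of a (normalized) signal, same length.

    The window is truncated at the record edges and the normalization runs
    over the available points only, so every output is a convex combination
    of the samples inside its window.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D sequence")
    n = params.half_width
    win = _padded_windows(x, n)                       # (L, 2N+1) with NaN edges
    valid = ~np.isnan(win)
    counts = valid.sum(axis=1)

    mean = np.nansum(win, axis=1) / counts
    var = np.nansum((win - mean[:, None]) ** 2 * valid, axis=1) / counts
    v = np.minimum(var, params.sigma2_max) if params.clamp else var
    g = np.log2(v / params.sigma2_max + 1.0)
    sigma_d = g * params.sigma_d_max + params.sigma_min
    sigma_r = g * params.sigma_r_max + params.sigma_min

    offsets = np.arange(-n, n + 1, dtype=float)
    w_dom = np.exp(-(offsets[None, :] ** 2) / (2.0 * sigma_d[:, None] ** 2))
    diff = win - x[:, None]
    with np.errstate(invalid="ignore"):
        w_rng = np.exp(-(diff ** 2) / (2.0 * sigma_r[:, None] ** 2))
    w = np.where(valid, w_dom * w_rng, 0.0)
    wp = w.sum(axis=1)
    return np.einsum("ij,ij->i", w, np.where(valid, win, 0.0)) / wp
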