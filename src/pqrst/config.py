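"""Sampling context and the detector's tunable constants.

Every duration-valued constant is stored in seconds and converted to a
sample count through :class:`SamplingContext`, so that records sampled at
rates other than the 360 Hz reference (e.g. 250 Hz ambulatory records)
are handled without retuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

REFERENCE_FS = 360.0


@dataclass(frozen=True)
class SamplingContext:
    """Sampling rate plus the sample-count scalings derived from it."""

    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def samples(self, seconds: float) -> int:
        """Convert a duration in seconds to a sample count (rounded)."""
        return int(round(seconds * self.fs))

    def seconds(self, samples: int) -> float:
        return samples / self.fs

    def scale_count(self, count_at_reference: int) -> int:
        """Rescale a sample count stated at the 360 Hz reference rate."""
        return max(1, int(round(count_at_reference * self.fs / REFERENCE_FS)))


@dataclass
class DetectorConfig:
    """Every tunable constant of the PQRST detector.

    Defaults are the published operating point at 360 Hz; duration-valued
    entries are seconds and are converted per record via SamplingContext.
    """

    # -- bilateral background predictor --------------------------------
    filter_half_width: int = 7          # window is 2N+1 = 15 samples
    sigma_d_max: float = 10.0
    sigma_r_max: float = 1.0
    sigma_min: float = 1e-5
    sigma2_max: float = 0.1310          # variance ceiling of the normalized signal
    clamp_sigmas: bool = False          # experimental: clamp variance at sigma2_max

    # -- residual enhancement / candidate-R ----------------------------
    enhance_half_width_ref: int = 5     # half-width of the moving sum, at 360 Hz
    min_run_ref: int = 8                # L >= 8 consecutive supra-threshold samples, at 360 Hz
    thc_ratio: float = 0.5              # Thc = thc_ratio * max|E| per window
    refractory_sec: float = 0.2         # merge candidate runs whose peaks collide

    # -- fragmented-R ---------------------------------------------------
    th_f: float = 0.1                   # rebound-amplitude threshold (normalized units)
    fragment_sum_terms: int = 10
    qrs_sec: float = 0.12               # typical QRS duration
    # alpha_f = round(0.5 * fs * qrs_sec)

    # -- Q/S search -----------------------------------------------------
    alpha_qm: int = 8                   # additive margin of the Q search range
    # alpha_q = round(fs * qrs_sec / 2) + alpha_qm ; alpha_s = alpha_q
    # alpha_ql = alpha_sr = round(fs * qrs_sec)

    # -- P/T point filters ----------------------------------------------
    pr_sec: float = 0.2                 # typical PR interval -> alpha_p
    qt_sec: float = 0.44                # typical QT interval -> alpha_t = fs*(QT-QRS)
    p_wing_ref: int = 10                # lP = rP = p_wing_ref - v
    t_wing_ref: int = 20                # lT = rT = t_wing_ref - v
    rho_p: float = 0.95
    rho_t: float = 0.95
    v_p_max: int = 5
    v_t_max: int = 10
    bound_outer_wing: int = 2           # onset/offset asymmetric wings
    bound_inner_wing: int = 4
    normalize_mode: str = "minmax"      # or "literal_eq1": divide by Smax as printed

    # -- sliding windows -------------------------------------------------
    window_len_ref: int = 2000          # samples at 360 Hz
    window_step_ref: int = 1600
    stitch_tolerance_ms: float = 50.0

    # -- HRV --------------------------------------------------------------
    hrv_resample_hz: float = 4.0
    hrv_welch_sec: float = 120.0
    hrv_bin_width_s: float = 1.0 / 128.0  # RR histogram bin for HTI/TINN
    rr_filter: bool = False               # optional exclusion of RR outside [0.2, 3] s
    rr_filter_range: tuple = (0.2, 3.0)

    # -- evaluation --------------------------------------------------------
    match_tolerance_ms: float = 50.0
    t_onset_exclusion_sec: float = 0.05

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DetectorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rr_filter_range" in data:
            data["rr_filter_range"] = tuple(data["rr_filter_range"])
        return cls(**data)


DEFAULT_CONFIG = DetectorConfig()
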