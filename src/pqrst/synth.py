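"""Synthetic single-lead ECG records with exact ground-truth fiducials.

Each beat is a sum of compactly supported Gaussian bumps, one per wave
component (P, Q, R, S, T).  A bump of amplitude A, center c and width w is

    g(t) = A * (exp(-(t-c)^2 / 2w^2) - eps) / (1 - eps)   for |t-c| <= w*sqrt(-2 ln eps)
    g(t) = 0                                              outside,

with eps = 0.01, i.e. the raw Gaussian shifted and rescaled so it reaches
exactly zero where its envelope falls to 1% of the amplitude.  The support
edges are therefore analytic and serve as the true onsets/offsets; outside
them the signal is exactly flat, which is what makes toe-finding slope
filters testable at sample precision.  Apex/trough truths (R, Q, S, P, T
peaks and fragment notches) are taken from the rendered clean composite,
so overlap between components is accounted for exactly.

Fragment patterns plant secondary bumps inside the QRS following the
notched-R taxonomy (fR-L, fR-R, fR-L2, fR-R2) plus a flat-top variant; T
shapes cover normal, inverted, biphasic, hyperacute and plateau apexes
(the plateau exercises the point filter's v-recursion).  Optional additive
white Gaussian noise is calibrated to a stated SNR in dB over the record,
and baseline wander is a slow sinusoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

ENVELOPE_EPS = 0.01
_TOE = math.sqrt(-2.0 * math.log(ENVELOPE_EPS))   # support half-width in units of w


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian bump: amplitude (mV), center offset from R (s), width (s)."""

    amplitude: float
    center: float
    width: float


@dataclass(frozen=True)
class SyntheticBeatSpec:
    """Morphology of one synthetic beat.

    Amplitudes are millivolts, times are seconds relative to the R apex.
    ``fragment_rebound`` scales the planted notch bumps relative to the R
    amplitude; ``t_plateau_halfwidth`` is the plateau half-width in samples
    for t_shape="plateau".
    """

    p: WaveComponent = WaveComponent(0.15, -0.170, 0.020)
    q: WaveComponent = WaveComponent(-0.10, -0.035, 0.008)
    r: WaveComponent = WaveComponent(1.00, 0.0, 0.015)
    s: WaveComponent = WaveComponent(-0.15, 0.035, 0.008)
    t: WaveComponent = WaveComponent(0.30, 0.250, 0.026)
    r_polarity: int = 1
    fragment_pattern: str = "none"   # none | fR-L | fR-R | fR-L2 | fR-R2 | flat
    fragment_rebound: float = 0.3
    fragment_center: float = 0.025   # first notch offset from R (s)
    fragment_spacing: float = 0.025  # offset between stacked notches (s)
    fragment_width: float = 0.004
    t_shape: str = "normal"          # normal | inverted | biphasic | hyperacute | plateau
    t_plateau_halfwidth: int = 3
    p_present: bool = True
    rr_interval: float = 0.8

    def __post_init__(self) -> None:
        for c in (self.p, self.q, self.r, self.s, self.t):
            if c.width <= 0:
                raise ValueError("component widths must be positive")
        if self.r_polarity not in (1, -1):
            raise ValueError("r_polarity must be +1 or -1")
        if self.fragment_pattern not in ("none", "fR-L", "fR-R", "fR-L2", "fR-R2", "flat"):
            raise ValueError(f"unknown fragment_pattern {self.fragment_pattern!r}")
        if self.t_shape not in ("normal", "inverted", "biphasic", "hyperacute", "plateau"):
            raise ValueError(f"unknown t_shape {self.t_shape!r}")
        if self.rr_interval <= self.beat_support():
            raise ValueError("rr_interval must exceed the beat support")

    def support_bounds(self) -> tuple[float, float]:
        comps = [self.q, self.r, self.s, self.t] + ([self.p] if self.p_present else [])
        lo = min(c.center - _TOE * c.width for c in comps)
        hi = max(c.center + _TOE * c.width for c in comps)
        return lo, hi

    def beat_support(self) -> float:
        lo, hi = self.support_bounds()
        return hi - lo


@dataclass
class GroundTruth:
    """True fiducials (record-absolute sample indices) of one beat."""

    fiducials: dict[str, int]
    gamma: int
    omega_p: int
    omega_t: int
    additional_left: list[int] = field(default_factory=list)
    additional_right: list[int] = field(default_factory=list)

    def ordered(self) -> bool:
        from .delineation import FIDUCIAL_NAMES
        vals = [self.fiducials[n] for n in FIDUCIAL_NAMES]
        return all(a <= b for a, b in zip(vals, vals[1:]))

    def shift(self, offset: int) -> "GroundTruth":
        return GroundTruth(
            fiducials={k: int(v + offset) for k, v in self.fiducials.items()},
            gamma=self.gamma, omega_p=self.omega_p, omega_t=self.omega_t,
            additional_left=[int(i + offset) for i in self.additional_left],
            additional_right=[int(i + offset) for i in self.additional_right],
        )


def _bump(t: np.ndarray, comp: WaveComponent) -> np.ndarray:
    """Compact-support Gaussian bump; exactly zero outside the 1% envelope."""
    half = _TOE * comp.width
    out = np.zeros_like(t)
    inside = np.abs(t - comp.center) <= half
    g = np.exp(-((t[inside] - comp.center) ** 2) / (2.0 * comp.width ** 2))
    out[inside] = comp.amplitude * (g - ENVELOPE_EPS) / (1.0 - ENVELOPE_EPS)
    return out


def _effective_t(spec: SyntheticBeatSpec) -> list[WaveComponent]:
    t = spec.t
    if spec.t_shape == "normal":
        return [t]
    if spec.t_shape == "inverted":
        return [replace(t, amplitude=-t.amplitude)]
    if spec.t_shape == "hyperacute":
        return [replace(t, amplitude=2.0 * t.amplitude, width=1.3 * t.width)]
    if spec.t_shape == "biphasic":
        return [replace(t, center=t.center - 1.8 * t.width),
                replace(t, amplitude=-0.8 * t.amplitude, center=t.center + 1.8 * t.width)]
    return [t]    # plateau: rendered as normal, apex flattened afterwards


def _fragment_components(spec: SyntheticBeatSpec) -> tuple[list[WaveComponent], list[str]]:
    a = spec.fragment_rebound * abs(spec.r.amplitude) * spec.r_polarity
    c1, c2 = spec.fragment_center, spec.fragment_center + spec.fragment_spacing
    mk = lambda c: WaveComponent(a, c, spec.fragment_width)
    if spec.fragment_pattern == "fR-R":
        return [mk(c1)], ["right"]
    if spec.fragment_pattern == "fR-L":
        return [mk(-c1)], ["left"]
    if spec.fragment_pattern == "fR-R2":
        return [mk(c1), mk(c2)], ["right", "right"]
    if spec.fragment_pattern == "fR-L2":
        return [mk(-c1), mk(-c2)], ["left", "left"]
    return [], []


def synthesize_beat(spec: SyntheticBeatSpec, fs: float) -> tuple[np.ndarray, GroundTruth]:
    """Render one beat and its exact ground truth (beat-relative indices).

    The returned truth indices are relative to the rendered beat array,
    whose sample 0 sits at ``spec.support_bounds()[0]`` rounded to the
    sample grid.
    """
    lo, hi = spec.support_bounds()
    i0 = math.floor(lo * fs) - 1
    i1 = math.ceil(hi * fs) + 1
    idx = np.arange(i0, i1 + 1)
    t = idx / fs

    comps: dict[str, list[WaveComponent]] = {
        "q": [spec.q], "r": [spec.r], "s": [spec.s],
        "t": _effective_t(spec),
        "p": [spec.p] if spec.p_present else [],
    }
    frag_comps, frag_sides = _fragment_components(spec)

    rendered: dict[str, np.ndarray] = {}
    total = np.zeros_like(t)
    for name, clist in comps.items():
        y = np.zeros_like(t)
        for c in clist:
            y += _bump(t, c)
        rendered[name] = y
        total += y
    frag_waves = [_bump(t, c) for c in frag_comps]
    for y in frag_waves:
        total += y

    if spec.r_polarity < 0:
        total = -total
        rendered = {k: -v for k, v in rendered.items()}
        frag_waves = [-y for y in frag_waves]

    def apex(name: str, signed: float) -> Optional[int]:
        sub = np.flatnonzero(np.abs(rendered[name]) > 0)
        if sub.size == 0:
            return None
        seg = total[sub]
        return int(sub[np.argmax(seg) if signed > 0 else np.argmin(seg)])

    gamma = spec.r_polarity
    r_apex = apex("r", gamma)

    if spec.fragment_pattern == "flat":
        v = max(1, spec.t_plateau_halfwidth)
        total[r_apex - v:r_apex + v + 1] = total[r_apex - v]
        ties = np.flatnonzero(total == total[r_apex])
        r_apex = int(math.floor(ties.mean()))

    if spec.t_shape == "plateau":
        t_sup = np.flatnonzero(np.abs(rendered["t"]) > 0)
        omega_t_sign = 1 if spec.t.amplitude * gamma > 0 else -1
        t_apex0 = int(t_sup[np.argmax(omega_t_sign * total[t_sup])])
        v = spec.t_plateau_halfwidth
        total[t_apex0 - v:t_apex0 + v + 1] = total[t_apex0 - v]

    def toe(name: str, side: int) -> Optional[int]:
        sup = np.flatnonzero(np.abs(rendered[name]) > 0)
        if sup.size == 0:
            return None
        return int(sup[0] - 1) if side < 0 else int(sup[-1] + 1)

    fid: dict[str, int] = {}
    fid["r_peak"] = r_apex
    # an absent Q (zero amplitude) collapses Q fiducials onto the QRS onset
    q_toes = [v for v in (toe("q", -1), toe("r", -1)) if v is not None]
    s_toes = [v for v in (toe("s", +1), toe("r", +1)) if v is not None]
    fid["q_onset"] = min(q_toes)
    fid["s_offset"] = max(s_toes)
    fid["q_peak"] = apex("q", -gamma) if apex("q", -gamma) is not None else fid["q_onset"]
    fid["s_peak"] = apex("s", -gamma) if apex("s", -gamma) is not None else fid["s_offset"]

    omega_t = 1 if (sum(c.amplitude for c in comps["t"][:1]) * gamma) > 0 else -1
    if spec.t_shape == "biphasic":
        omega_t = 1 if gamma > 0 else -1   # positive lobe is the annotated peak
    t_sup = np.flatnonzero(np.abs(rendered["t"]) > 0)
    fid["t_peak"] = int(t_sup[np.argmax(omega_t * total[t_sup])])
    if spec.t_shape == "plateau":
        plateau = np.flatnonzero(total == total[fid["t_peak"]])
        plateau = plateau[(plateau >= t_sup[0]) & (plateau <= t_sup[-1])]
        fid["t_peak"] = int(math.floor(plateau.mean()))
    fid["t_onset"] = toe("t", -1)
    fid["t_offset"] = toe("t", +1)

    if spec.p_present:
        omega_p = 1 if spec.p.amplitude * gamma > 0 else -1
        p_sup = np.flatnonzero(np.abs(rendered["p"]) > 0)
        fid["p_peak"] = int(p_sup[np.argmax(omega_p * total[p_sup])])
        fid["p_onset"] = toe("p", -1)
        fid["p_offset"] = toe("p", +1)
    else:
        omega_p = 1
        fid["p_onset"] = fid["p_peak"] = fid["p_offset"] = fid["q_onset"]

    extra_left: list[int] = []
    extra_right: list[int] = []
    d1 = np.empty(total.size)
    d1[:-1] = total[:-1] - total[1:]
    d1[-1] = 0.0
    for y, side in zip(frag_waves, frag_sides):
        # the true notch apex is the gamma-oriented local maximum the bump
        # imprints on the composite (the QRS flank shifts it off the bump
        # center, so the apex is located on the rendered waveform)
        sup = np.flatnonzero(np.abs(y) > 0)
        sup = sup[(sup >= 1) & (sup <= total.size - 2)]
        is_apex = (gamma * d1[sup - 1] < 0) & (gamma * d1[sup] > 0)
        apexes = sup[is_apex]
        if apexes.size == 0:
            raise ValueError("planted notch leaves no detectable apex on the flank")
        a = int(apexes[np.argmax(gamma * total[apexes])])
        (extra_right if side == "right" else extra_left).append(a)
    extra_left.sort(reverse=True)   # ordered moving away from R
    extra_right.sort()

    truth = GroundTruth(fiducials={k: v - 0 for k, v in fid.items()},
                        gamma=gamma, omega_p=omega_p, omega_t=omega_t,
                        additional_left=extra_left, additional_right=extra_right)
    if not truth.ordered():
        raise ValueError("component layout violates the fiducial ordering invariant")
    return total, truth


def synthesize_record(spec: SyntheticBeatSpec, n_beats: int, fs: float,
                      rr_jitter: float = 0.0,
                      noise_snr_db: Optional[float] = None,
                      baseline_amplitude: float = 0.0,
                      baseline_freq: float = 0.25,
                      seed: int = 0,
                      pad_sec: float = 0.35,
                      ) -> tuple[np.ndarray, list[GroundTruth]]:
    """A record of ``n_beats`` concatenated beats plus truth.

    ``rr_jitter`` is the standard deviation (s) of Gaussian RR perturbation;
    ``noise_snr_db`` adds white Gaussian noise at that record-level SNR
    (10*log10 of AC signal power over noise power); baseline wander is a
    sinusoid of the given amplitude (mV) and frequency (Hz).  Seeded
    generation is bit-reproducible.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    rng = np.random.default_rng(seed)

    beat, truth0 = synthesize_beat(spec, fs)
    lo, _ = spec.support_bounds()
    beat_start_rel = math.floor(lo * fs) - 1   # beat sample 0 relative to R apex

    rr = np.full(n_beats, spec.rr_interval)
    if rr_jitter > 0:
        rr = rr + rng.normal(0.0, rr_jitter, size=n_beats)
        rr = np.clip(rr, spec.beat_support() + 0.05, None)
    r_times = np.concatenate([[pad_sec - beat_start_rel / fs], np.cumsum(rr[:-1])])
    r_times[1:] += r_times[0]
    r_indices = np.round(r_times * fs).astype(int)

    length = int(r_indices[-1] + beat.size + beat_start_rel + round(pad_sec * fs))
    x = np.zeros(length)
    truths: list[GroundTruth] = []
    for ri in r_indices:
        a = ri + beat_start_rel
        x[a:a + beat.size] += beat
        truths.append(truth0.shift(a))

    if baseline_amplitude != 0.0:
        tt = np.arange(length) / fs
        phase = rng.uniform(0, 2 * math.pi)
        x = x + baseline_amplitude * np.sin(2 * math.pi * baseline_freq * tt + phase)

    if noise_snr_db is not None:
        p_sig = float(np.mean((x - x.mean()) ** 2))
        p_noise = p_sig / (10.0 ** (noise_snr_db / 10.0))
        x = x + rng.normal(0.0, math.sqrt(p_noise), size=length)

    return x, truths
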