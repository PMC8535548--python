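import numpy as np
import pytest

from pqrst import (DetectorConfig, SyntheticBeatSpec, bilateral_filter,
                   detect_record, normalize_window, synthesize_record)
from pqrst.config import SamplingContext
from pqrst.delineation import (BeatFiducials, FIDUCIAL_NAMES, PointFilterParams,
                               SearchRanges, WaveCandidate, detect_q, detect_q_onset,
                               detect_s, detect_s_offset, detect_wave_bounds,
                               detect_wave_peak, map_missing_fps, select_wave_polarity)
from pqrst.rpeak import RPeakInfo
from pqrst.synth import WaveComponent, _bump

FS = 360.0


def _setup(spec=None, n_beats=3, seed=5):
    spec = spec or SyntheticBeatSpec()
    x, truths = synthesize_record(spec, n_beats, FS, seed=seed)
    w = normalize_window(x)
    return w, bilateral_filter(w.samples), truths


def _ranges(config):
    return SearchRanges.from_context(SamplingContext(FS), config)


def _bump_on_flat(length=400, center=200.0, width=10.0, amplitude=1.0):
    t = np.arange(length, dtype=float)
    return _bump(t, WaveComponent(amplitude, center, width))


class TestSearchRanges:
    def test_reference_rate_sample_counts(self, config):
        r = _ranges(config)
        # round(360*0.12/2)+8, round(360*0.12), round(360*0.2), round(360*0.32)
        assert (r.alpha_q, r.alpha_ql, r.alpha_p, r.alpha_t) == (30, 43, 72, 115)
        assert r.alpha_s == r.alpha_q and r.alpha_sr == r.alpha_ql
        assert r.alpha_f == 22


class TestQandS:
    def test_planted_q_and_s_recovered(self, config):
        w, _, truths = _setup()
        t = truths[1]
        r = RPeakInfo(index=t.fiducials["r_peak"], gamma=t.gamma)
        q, q_m = detect_q(w, r, _ranges(config))
        s, s_m = detect_s(w, r, _ranges(config))
        assert (q, q_m) == (t.fiducials["q_peak"], False)
        assert (s, s_m) == (t.fiducials["s_peak"], False)

    def test_onset_and_offset_shoulders_recovered(self, config):
        w, _, truths = _setup()
        t = truths[1]
        gamma = t.gamma
        q_on, m1 = detect_q_onset(w, t.fiducials["q_peak"], gamma, _ranges(config))
        s_off, m2 = detect_s_offset(w, t.fiducials["s_peak"], gamma, _ranges(config))
        assert (q_on, m1) == (t.fiducials["q_onset"], False)
        assert (s_off, m2) == (t.fiducials["s_offset"], False)

    def test_monotone_flank_maps_to_range_end(self, config):
        # no Q trough at all: R rises straight out of a flat baseline
        spec = SyntheticBeatSpec(q=WaveComponent(0.0, -0.035, 0.008),
                                 s=WaveComponent(0.0, 0.035, 0.008))
        w, _, truths = _setup(spec)
        t = truths[1]
        r = RPeakInfo(index=t.fiducials["r_peak"], gamma=1)
        q, q_m = detect_q(w, r, _ranges(config))
        assert q_m and q == r.index - _ranges(config).alpha_q

    def test_time_reversal_swaps_q_and_s(self, config):
        w, _, truths = _setup()
        t = truths[1]
        rev = normalize_window(w.samples[::-1].copy())
        n = w.samples.size
        r_fwd = RPeakInfo(index=t.fiducials["r_peak"], gamma=t.gamma)
        r_rev = RPeakInfo(index=n - 1 - t.fiducials["r_peak"], gamma=t.gamma)
        q, _ = detect_q(w, r_fwd, _ranges(config))
        s_rev, _ = detect_s(rev, r_rev, _ranges(config))
        assert s_rev == n - 1 - q
        q_on, _ = detect_q_onset(w, q, t.gamma, _ranges(config))
        s_off_rev, _ = detect_s_offset(rev, s_rev, t.gamma, _ranges(config))
        assert s_off_rev == n - 1 - q_on

    def test_inverted_beat_mirrors_q(self, config):
        w, _, truths = _setup()
        t = truths[1]
        flipped = normalize_window(1.0 - w.samples)
        r = RPeakInfo(index=t.fiducials["r_peak"], gamma=t.gamma)
        r_inv = RPeakInfo(index=t.fiducials["r_peak"], gamma=-t.gamma)
        q, _ = detect_q(w, r, _ranges(config))
        q_inv, _ = detect_q(flipped, r_inv, _ranges(config))
        assert q_inv == q


class TestWavePeakFilter:
    def test_symmetric_bump_apex(self, config):
        b = _bump_on_flat()
        params = PointFilterParams.for_wave("T", config)
        hit = detect_wave_peak(b, (150, 260), "T", params)
        assert hit is not None
        idx, omega, v_true = hit
        assert omega == 1 and v_true == 0
        assert abs(idx - 200) <= 1

    def test_negated_bump_detected_as_inverted(self, config):
        b = -_bump_on_flat()
        params = PointFilterParams.for_wave("T", config)
        idx, omega, v_true = detect_wave_peak(b, (150, 260), "T", params)
        assert omega == -1 and v_true == 0 and abs(idx - 200) <= 1

    def test_leftward_scan_finds_same_apex(self, config):
        b = _bump_on_flat()
        params = PointFilterParams.for_wave("P", config)
        idx, omega, _ = detect_wave_peak(b, (260, 150), "P", params)
        assert omega == 1 and abs(idx - 200) <= 1

    def test_flat_region_never_fires(self, config):
        b = np.zeros(400)
        params = PointFilterParams.for_wave("T", config)
        assert detect_wave_peak(b, (100, 300), "T", params) is None

    def test_exact_plateau_fires_centered(self, config):
        # sign(0) passes both wing inequalities, so an exactly flat apex is
        # accepted at v=0 and the tie-break centers it
        b = _bump_on_flat()
        b[198:203] = b[198]
        params = PointFilterParams.for_wave("T", config)
        idx, omega, v_true = detect_wave_peak(b, (150, 260), "T", params)
        assert omega == 1 and v_true == 0
        assert abs(idx - 200) <= 1

    def test_dented_apex_needs_v_recursion_and_v_is_minimal(self, config):
        # a wrong-sign ripple around the apex defeats v=0; v_true must be
        # the smallest deformation at which the filter fires
        b = _bump_on_flat() - _bump_on_flat(center=200.0, width=2.0, amplitude=0.25)
        params = PointFilterParams.for_wave("T", config)
        hit = detect_wave_peak(b, (150, 260), "T", params)
        assert hit is not None
        _, _, v_true = hit
        assert v_true >= 1
        fires_at = []
        for v in range(params.v_max + 1):
            p = PointFilterParams(params.wing_ref, params.rho, v)
            if detect_wave_peak(b, (150, 260), "T", p) is not None:
                fires_at.append(v)
        assert v_true == min(fires_at)


class TestWaveBounds:
    def test_toes_of_symmetric_bump(self, config):
        b = _bump_on_flat(center=200.0, width=10.0)
        params = PointFilterParams.for_wave("T", config)
        support = np.flatnonzero(np.abs(b) > 0)
        true_on, true_off = support[0] - 1, support[-1] + 1
        onset = detect_wave_bounds(b, 200, 1, 0, "onset", "T", 150, params)
        offset = detect_wave_bounds(b, 200, 1, 0, "offset", "T", 150, params)
        assert abs(onset - true_on) <= 1
        assert abs(offset - true_off) <= 1

    def test_inverted_bump_mirrored_toes(self, config):
        b = -_bump_on_flat(center=200.0, width=10.0)
        params = PointFilterParams.for_wave("T", config)
        support = np.flatnonzero(np.abs(b) > 0)
        onset = detect_wave_bounds(b, 200, -1, 0, "onset", "T", 150, params)
        offset = detect_wave_bounds(b, 200, -1, 0, "offset", "T", 150, params)
        assert abs(onset - (support[0] - 1)) <= 1
        assert abs(offset - (support[-1] + 1)) <= 1

    def test_truncated_range_returns_none(self, config):
        b = _bump_on_flat(length=230, center=200.0, width=10.0)
        params = PointFilterParams.for_wave("T", config)
        # offset scan hits the array end before any toe qualifies
        assert detect_wave_bounds(b, 200, 1, 0, "offset", "T", 195, params) is None


class TestPolaritySelection:
    def _cand(self, onset, peak, offset, omega):
        return WaveCandidate(onset, peak, offset, omega, 0)

    def test_single_candidate_wins(self):
        b = np.zeros(100)
        c = self._cand(10, 20, 30, 1)
        assert select_wave_polarity(c, None, b) is c
        assert select_wave_polarity(None, c, b) is c

    def test_wide_deep_inverted_beats_narrow_ripple(self):
        b = np.zeros(100)
        b[40:61] = -np.sin(np.linspace(0, np.pi, 21))          # deep wide trough
        b[20:25] = 0.05 * np.sin(np.linspace(0, np.pi, 5))     # shallow ripple
        normal = self._cand(20, 22, 24, 1)
        inverted = self._cand(40, 50, 60, -1)
        assert select_wave_polarity(normal, inverted, b) is inverted

    def test_wider_but_smaller_area_keeps_normal(self):
        b = np.zeros(100)
        b[20:31] = np.sin(np.linspace(0, np.pi, 11))           # tall normal wave
        b[40:71] = -0.01 * np.sin(np.linspace(0, np.pi, 31))   # wide shallow dip
        normal = self._cand(20, 25, 30, 1)
        inverted = self._cand(40, 55, 70, -1)
        assert select_wave_polarity(normal, inverted, b) is normal


class TestMapping:
    def _beat(self, **kw):
        base = dict(p_onset=10, p_peak=15, p_offset=20, q_onset=25, q_peak=28,
                    r_peak=32, s_peak=36, s_offset=40, t_onset=50, t_peak=60,
                    t_offset=70)
        base.update(kw)
        return BeatFiducials(**base)

    def test_fully_detected_beat_is_identity(self):
        beat = map_missing_fps(self._beat())
        assert beat.mapped == set() and beat.ordered()

    def test_absent_p_collapses_onto_q_onset(self):
        beat = map_missing_fps(self._beat(p_onset=-1, p_peak=-1, p_offset=-1))
        assert beat.p_onset == beat.p_peak == beat.p_offset == beat.q_onset
        assert beat.mapped == {"p_onset", "p_peak", "p_offset"}
        assert beat.ordered()

    def test_missing_t_offset_maps_to_t_peak(self):
        beat = map_missing_fps(self._beat(t_offset=-1))
        assert beat.t_offset == beat.t_peak and beat.mapped == {"t_offset"}

    def test_missing_t_onset_maps_to_s_offset(self):
        beat = map_missing_fps(self._beat(t_onset=-1))
        assert beat.t_onset == beat.s_offset and beat.mapped == {"t_onset"}

    def test_pipeline_totality_without_p_wave(self, config):
        spec = SyntheticBeatSpec(p_present=False)
        x, truths = synthesize_record(spec, 10, FS, seed=4)
        beats = detect_record(x, FS, config)
        assert len(beats) == len(truths)
        for b in beats:
            f = b.fiducials
            assert f.p_onset == f.p_peak == f.p_offset == f.q_onset
            assert {"p_onset", "p_peak", "p_offset"} <= f.mapped
            assert f.ordered()


class TestParameterRecovery:
    @pytest.mark.parametrize("spec, omega_t", [
        (SyntheticBeatSpec(), 1),
        (SyntheticBeatSpec(t_shape="inverted"), -1),
    ])
    def test_clean_beats_recover_planted_fiducials(self, spec, omega_t, config):
        x, truths = synthesize_record(spec, 10, FS, seed=8)
        beats = detect_record(x, FS, config)
        ref = np.array([t.fiducials["r_peak"] for t in truths])
        assert len(beats) == len(truths)
        for b in beats:
            t = truths[int(np.argmin(np.abs(ref - b.r_index)))]
            f = b.fiducials
            assert abs(f.p_peak - t.fiducials["p_peak"]) <= 1
            assert abs(f.t_peak - t.fiducials["t_peak"]) <= 1
            for name in ("p_onset", "p_offset", "t_onset", "t_offset"):
                assert abs(getattr(f, name) - t.fiducials[name]) <= 3
            assert f.t_omega == omega_t
            assert f.ordered() and not f.mapped
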