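import json

import numpy as np
import pytest
from click.testing import CliRunner
from hypothesis import given, settings, strategies as st

from pqrst import (DetectorConfig, EvalCounts, SyntheticBeatSpec, detection_metrics,
                   match_annotations, rmse_stats, synthesize_record)
from pqrst.cli import main as cli_main
from pqrst.io import (RecordParseError, annotation_table, read_annotations,
                      read_record, write_annotations, write_record)
from pqrst.windowing import detect_record

FS = 360.0


class TestMatching:
    def test_within_tolerance_is_tp(self):
        c = match_annotations([110], [100], FS)
        assert (c.tp, c.fn, c.fp) == (1, 0, 0)

    def test_beyond_tolerance_is_fn_plus_fp(self):
        c = match_annotations([120], [100], FS)   # 55.6 ms apart
        assert (c.tp, c.fn, c.fp) == (0, 1, 1)

    def test_missed_beats_are_fn(self):
        c = match_annotations([], [100, 400, 700], FS)
        assert (c.tp, c.fn, c.fp) == (0, 3, 0)

    def test_each_annotation_matched_once(self):
        c = match_annotations([100, 104], [102], FS)
        assert (c.tp, c.fn, c.fp) == (1, 0, 1)

    @given(st.lists(st.integers(0, 5000), max_size=20),
           st.lists(st.integers(0, 5000), max_size=20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_swapping_lists_swaps_fn_and_fp(self, det, ref):
        a = match_annotations(det, ref, FS)
        b = match_annotations(ref, det, FS)
        assert (a.tp, a.fn, a.fp) == (b.tp, b.fp, b.fn)

    def test_tolerance_is_in_time_not_samples(self):
        # 40 ms offset: 14.4 samples at 360 Hz, 10 at 250 Hz; both match
        for fs in (360.0, 250.0):
            off = int(round(0.040 * fs))
            c = match_annotations([1000 + off], [1000], fs)
            assert c.tp == 1


class TestDetectionMetrics:
    @pytest.mark.parametrize("total, fn, fp, se, pp, der", [
        (109510, 184, 193, 99.83, 99.82, 0.34),
        (1774, 13, 23, 99.27, 98.71, 2.03),
        (2980, 13, 15, 99.56, 99.50, 0.94),
    ])
    def test_reference_count_arithmetic(self, total, fn, fp, se, pp, der):
        counts = EvalCounts(tp=total - fn, fn=fn, fp=fp)
        got = detection_metrics(counts)
        assert round(got[0], 2) == se
        assert round(got[1], 2) == pp
        assert round(got[2], 2) == der

    def test_perfect_detection(self):
        assert detection_metrics(EvalCounts(tp=10, fn=0, fp=0)) == (100.0, 100.0, 0.0)

    def test_no_annotations_is_an_error(self):
        with pytest.raises(ValueError):
            detection_metrics(EvalCounts(tp=0, fn=0, fp=5))


class TestRmseStats:
    @pytest.mark.parametrize("m, s, rmse", [(1.8, 3.3, 3.8), (0.2, 0.3, 0.4)])
    def test_mean_std_pairs_reproduce_rmse(self, m, s, rmse):
        # two-point series with exactly the given mean and population std
        stats = rmse_stats([m - s, m + s])
        assert stats.mean_ms == pytest.approx(m)
        assert stats.std_ms == pytest.approx(s)
        assert round(stats.rmse_ms, 1) == rmse

    def test_zero_errors(self):
        stats = rmse_stats([0.0, 0.0, 0.0])
        assert (stats.mean_ms, stats.std_ms, stats.rmse_ms) == (0.0, 0.0, 0.0)

    def test_rmse_equals_root_mean_square(self, rng):
        e = rng.normal(2.0, 5.0, size=200)
        stats = rmse_stats(e)
        assert stats.rmse_ms == pytest.approx(np.sqrt(np.mean(e ** 2)))


class TestRecordIO:
    def test_csv_round_trip_bit_exact(self, tmp_path, rng):
        x = rng.normal(size=500)
        path = tmp_path / "rec.csv"
        write_record(path, x, FS)
        back, ctx = read_record(path)
        np.testing.assert_array_equal(back, x)
        assert ctx.fs == FS

    def test_missing_fs_is_an_error(self, tmp_path):
        path = tmp_path / "rec.csv"
        path.write_text("sample_index,mV\n0,0.1\n1,0.2\n")
        with pytest.raises(RecordParseError, match="sampling rate"):
            read_record(path)
        _, ctx = read_record(path, fs=250.0)
        assert ctx.fs == 250.0

    def test_malformed_line_names_position(self, tmp_path):
        path = tmp_path / "rec.csv"
        path.write_text("# fs=360\n0,0.1\n1,0.2,9\n")
        with pytest.raises(RecordParseError, match="3"):
            read_record(path)

    def test_annotation_round_trip(self, tmp_path, clean_record):
        x, _ = clean_record
        beats = detect_record(x, FS)
        path = tmp_path / "fps.json"
        write_annotations(path, beats, FS)
        back, fs = read_annotations(path)
        assert fs == FS and len(back) == len(beats)
        for a, b in zip(back, beats):
            assert a.fiducials.as_dict() == b.fiducials.as_dict()
            assert a.r.gamma == b.r.gamma
            assert a.fiducials.mapped == b.fiducials.mapped

    def test_annotation_table_layout(self, clean_record):
        x, _ = clean_record
        beats = detect_record(x, FS)
        table = annotation_table(beats, FS)
        assert len(table) == 11 * len(beats)
        assert (table["sample"].values == np.sort(table["sample"].values)).all()


class TestCli:
    def test_synth_detect_eval_hrv_round_trip(self, tmp_path):
        runner = CliRunner()
        rec = tmp_path / "rec.csv"
        truth = tmp_path / "truth.json"
        fps = tmp_path / "fps.json"
        hrv_out = tmp_path / "hrv.json"

        r = runner.invoke(cli_main, ["synth", "--n-beats", "20", "--seed", "4",
                                     "--rr-jitter", "0.03",
                                     "--out", str(rec), "--truth-out", str(truth)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["detect", str(rec), "--out", str(fps)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["eval", "--detected", str(fps),
                                     "--truth", str(truth)])
        assert r.exit_code == 0, r.output
        scores = json.loads(r.output)
        assert scores["se_pct"] == 100.0 and scores["pp_pct"] == 100.0
        r = runner.invoke(cli_main, ["hrv", str(fps), "--out", str(hrv_out),
                                     "--intervals-csv", str(tmp_path / "iv.csv")])
        assert r.exit_code == 0, r.output
        report = json.loads(hrv_out.read_text())
        assert report["RR mean"] == pytest.approx(0.8, abs=0.05)
        assert (tmp_path / "iv.csv").exists()

    def test_detect_honors_config_file(self, tmp_path):
        runner = CliRunner()
        cfg_path = tmp_path / "cfg.yaml"
        DetectorConfig(th_f=0.25).to_yaml(cfg_path)
        assert DetectorConfig.from_yaml(cfg_path).th_f == 0.25
        rec = tmp_path / "rec.csv"
        x, _ = synthesize_record(SyntheticBeatSpec(), 5, FS, seed=0)
        write_record(rec, x, FS)
        r = runner.invoke(cli_main, ["detect", str(rec), "--config", str(cfg_path),
                                     "--out", str(tmp_path / "f.json")])
        assert r.exit_code == 0, r.output
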