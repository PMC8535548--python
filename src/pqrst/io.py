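"""Record and annotation I/O.

The native record format is a two-column CSV (sample_index, millivolts)
with an optional header; the sampling rate travels either in a ``# fs=``
comment line or is supplied explicitly (it is never guessed).  Fiducial
annotations are JSON: a list of per-beat objects with the 11 named
fiducials, polarities and mapping flags.  WFDB records (.hea/.dat) are
read through the optional ``wfdb`` dependency when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import SamplingContext
from .delineation import BeatFiducials, FIDUCIAL_NAMES
from .rpeak import RPeakInfo
from .windowing import DetectedBeat


class RecordParseError(ValueError):
    pass


def write_record(path, samples, fs: float) -> None:
    """Write a record as CSV with an ``# fs=`` comment header."""
    x = np.asarray(samples, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"# fs={fs}\n")
        fh.write("sample_index,mV\n")
        for i, v in enumerate(x):
            fh.write(f"{i},{float(v)!r}\n")


def read_record(path, fmt: str = "csv",
                fs: Optional[float] = None) -> tuple[np.ndarray, SamplingContext]:
    """Read a record; returns (samples, SamplingContext).

    CSV: two columns (sample_index, millivolts), header optional, sampling
    rate from a ``# fs=`` comment or the ``fs`` argument — a missing rate
    is an error, never a guess.  "wfdb" reads a WFDB header/record pair
    (first signal channel) when the wfdb package is available.
    """
    path = Path(path)
    if fmt == "wfdb":
        try:
            import wfdb  # type: ignore
        except ImportError as exc:
            raise ImportError(
                "WFDB support requires the optional 'wfdb' package "
                "(pip install pqrst[wfdb])") from exc
        rec = wfdb.rdrecord(str(path.with_suffix("")))
        return rec.p_signal[:, 0].astype(float), SamplingContext(float(rec.fs))
    if fmt != "csv":
        raise ValueError(f"unknown record format {fmt!r}")

    file_fs = None
    rows: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("fs="):
                    file_fs = float(body[3:])
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise RecordParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                rows.append(float(parts[1]))
            except ValueError:
                if rows:
                    raise RecordParseError(f"{path}:{lineno}: malformed value {parts[1]!r}")
                continue  # header row
    if not rows:
        raise RecordParseError(f"{path}: no samples found")
    effective = fs if fs is not None else file_fs
    if effective is None:
        raise RecordParseError(
            f"{path}: sampling rate missing (no '# fs=' line and no --fs given)")
    return np.asarray(rows), SamplingContext(float(effective))


def beats_to_json(beats: list[DetectedBeat], fs: float) -> list[dict]:
    out = []
    for i, b in enumerate(beats):
        f = b.fiducials
        out.append({
            "beat_id": i,
            "fs": fs,
            "fiducials": f.as_dict(),
            "gamma": b.r.gamma,
            "omega_p": f.p_omega,
            "omega_t": f.t_omega,
            "v_p_true": f.v_p_true,
            "v_t_true": f.v_t_true,
            "is_flat": b.r.is_flat,
            "additional_left": list(b.r.additional_left),
            "additional_right": list(b.r.additional_right),
            "mapped": sorted(f.mapped),
        })
    return out


def write_annotations(path, beats: list[DetectedBeat], fs: float) -> None:
    with open(path, "w") as fh:
        json.dump({"fs": fs, "beats": beats_to_json(beats, fs)}, fh, indent=1)


def read_annotations(path) -> tuple[list[DetectedBeat], float]:
    """Read a fiducial JSON stream back into DetectedBeat objects."""
    with open(path) as fh:
        data = json.load(fh)
    fs = float(data["fs"])
    beats = []
    for rec in data["beats"]:
        fid = BeatFiducials(
            **{k: int(v) for k, v in rec["fiducials"].items()},
            p_omega=rec.get("omega_p", 1), t_omega=rec.get("omega_t", 1),
            v_p_true=rec.get("v_p_true", 0), v_t_true=rec.get("v_t_true", 0),
            mapped=set(rec.get("mapped", [])))
        r = RPeakInfo(index=fid.r_peak, gamma=rec.get("gamma", 1),
                      is_flat=rec.get("is_flat", False),
                      additional_left=list(rec.get("additional_left", [])),
                      additional_right=list(rec.get("additional_right", [])))
        beats.append(DetectedBeat(fiducials=fid, r=r))
    return beats, fs


def annotation_table(beats: list[DetectedBeat], fs: float) -> pd.DataFrame:
    """WFDB-style flat annotation table: one (sample, symbol) row per fiducial."""
    symbols = {"p_onset": "(p", "p_peak": "p", "p_offset": "p)",
               "q_onset": "(N", "q_peak": "Q", "r_peak": "N",
               "s_peak": "S", "s_offset": "N)",
               "t_onset": "(t", "t_peak": "t", "t_offset": "t)"}
    rows = []
    for i, b in enumerate(beats):
        for name in FIDUCIAL_NAMES:
            rows.append({"beat_id": i, "sample": getattr(b.fiducials, name),
                         "time_s": getattr(b.fiducials, name) / fs,
                         "fiducial": name, "symbol": symbols[name]})
    return pd.DataFrame(rows).sort_values(["sample", "beat_id"]).reset_index(drop=True)
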