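"""File dialects for recordings, feature tensors and cohort manifests.

Recordings travel as UTF-8 delimited text, one row per 100 Hz sample, with a
comment block carrying metadata — the same style as a serial-terminal capture
of the pen's USB stream::

    # subject_id: syn-CN-0001
    # task: spiral
    # label: CN
    # source: synthetic
    t,ax,ay,az,gx,gy,gz,mx,my,mz
    0.00,-0.0012,...

The magnetometer columns are optional.  Write-then-read round-trips are
value-identical (full float precision).  Malformed rows are reported with
their line number; out-of-range samples are rejected against the sensor
full-scale limits (+/-16 g, +/-2000 deg/s).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from penkinetics.features import CHANNEL_NAMES, FeatureTensor
from penkinetics.recording import ACCEL_RANGE_G, GYRO_RANGE_DPS, RawRecording

_REC_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")
_MAG_COLUMNS = ("mx", "my", "mz")
_FLOAT_FMT = "%.17g"


def write_recording(rec: RawRecording, path: Union[str, Path]) -> None:
    """Write a recording in the delimited dialect (lossless round-trip)."""
    path = Path(path)
    cols = list(_REC_COLUMNS) + (list(_MAG_COLUMNS) if rec.mag is not None else [])
    data = [rec.t, rec.accel[:, 0], rec.accel[:, 1], rec.accel[:, 2],
            rec.gyro[:, 0], rec.gyro[:, 1], rec.gyro[:, 2]]
    if rec.mag is not None:
        data += [rec.mag[:, 0], rec.mag[:, 1], rec.mag[:, 2]]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in ("subject_id", "task", "label", "source"):
            fh.write(f"# {key}: {getattr(rec, key)}\n")
        fh.write(",".join(cols) + "\n")
        np.savetxt(fh, np.column_stack(data), fmt=_FLOAT_FMT, delimiter=",")


def read_recording(path: Union[str, Path]) -> RawRecording:
    """Parse a recording file, validating layout, monotone time and ranges."""
    path = Path(path)
    meta = {"subject_id": path.stem, "task": "spiral", "label": "CN", "source": "real"}
    header: Optional[List[str]] = None
    rows: List[List[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    if key.strip() in meta:
                        meta[key.strip()] = value.strip()
                continue
            fields = [f.strip() for f in line.split(",")]
            if header is None:
                header = fields
                continue
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: malformed row ({exc})") from None
            if len(fields) != len(header):
                raise ValueError(
                    f"{path.name}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
    if header is None or not rows:
        raise ValueError(f"{path.name}: no data rows found")
    missing = [c for c in _REC_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    arr = np.asarray(rows, dtype=float)
    col = {name: arr[:, header.index(name)] for name in header}
    t = col["t"]
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path.name}: timestamps must be strictly increasing")
    accel = np.column_stack([col["ax"], col["ay"], col["az"]])
    gyro = np.column_stack([col["gx"], col["gy"], col["gz"]])
    if np.any(np.abs(accel) > ACCEL_RANGE_G):
        raise ValueError(
            f"{path.name}: accelerometer value exceeds the +/-{ACCEL_RANGE_G:g} g range"
        )
    if np.any(np.abs(gyro) > GYRO_RANGE_DPS):
        raise ValueError(
            f"{path.name}: gyroscope value exceeds the +/-{GYRO_RANGE_DPS:g} deg/s range"
        )
    mag = None
    if all(c in header for c in _MAG_COLUMNS):
        mag = np.column_stack([col[c] for c in _MAG_COLUMNS])
    return RawRecording(t=t, accel=accel, gyro=gyro, mag=mag, **meta)


def write_tensor(ft: FeatureTensor, path: Union[str, Path]) -> None:
    """Serialize a feature tensor as delimited text with a channel header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in ("subject_id", "task", "label", "source"):
            fh.write(f"# {key}: {getattr(ft, key)}\n")
        fh.write(f"# valid_length: {ft.valid_length}\n")
        fh.write(",".join(ft.channel_names) + "\n")
        np.savetxt(fh, ft.values, fmt=_FLOAT_FMT, delimiter=",")


def read_tensor(path: Union[str, Path]) -> FeatureTensor:
    path = Path(path)
    meta = {"subject_id": path.stem, "task": "spiral", "label": "CN", "source": "synthetic"}
    valid_length = None
    header = None
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                key, _, value = body.partition(":")
                key = key.strip()
                if key in meta:
                    meta[key] = value.strip()
                elif key == "valid_length":
                    valid_length = int(value)
                continue
            if header is None:
                header = [f.strip() for f in line.split(",")]
                continue
            rows.append([float(f) for f in line.split(",")])
    if header is None or not rows:
        raise ValueError(f"{path.name}: no data rows found")
    values = np.asarray(rows, dtype=float)
    if valid_length is None:
        valid_length = len(values)
    return FeatureTensor(values=values, valid_length=valid_length,
                         channel_names=tuple(header), **meta)


def write_manifest(items: Sequence, paths: Sequence[Union[str, Path]],
                   manifest_path: Union[str, Path]) -> None:
    """Write a cohort manifest (subject_id, task, label, source, file)."""
    df = pd.DataFrame({
        "subject_id": [it.subject_id for it in items],
        "task": [it.task for it in items],
        "label": [it.label for it in items],
        "source": [it.source for it in items],
        "path": [os.fspath(p) for p in paths],
    })
    df.to_csv(manifest_path, index=False)


def read_manifest(manifest_path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(manifest_path)


def write_cohort(cohort: Sequence[RawRecording], out_dir: Union[str, Path]) -> Path:
    """Write one file per recording plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in cohort:
        p = out_dir / f"{rec.subject_id}_{rec.task}.csv"
        write_recording(rec, p)
        paths.append(p)
    manifest = out_dir / "manifest.csv"
    write_manifest(cohort, paths, manifest)
    return manifest
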