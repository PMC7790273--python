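"""Plain-text on-disk formats: recordings, events, mood scales, feature tables.

A recording is a directory holding one TSV per wavelength (header row of
channel names, one line per sample) plus a small ``recording.yaml`` with the
sampling rate, subject id, wavelengths and the montage (channel/region list).
Events and mood files are single TSVs with fixed column names.  Everything is
diffable text; numeric round trips are exact to well below 1e-9.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    EVENT_COLUMNS,
    MoodScores,
    OpticalRecording,
    validate_trial_table,
)
from .errors import FormatError, ValidationError
from .montage import Montage

_FLOAT_FMT = "%.12g"

RECORDING_META = "recording.yaml"


def _intensity_filename(wavelength_nm: int) -> str:
    return f"intensity_{wavelength_nm}nm.tsv"


def write_recording(rec: OpticalRecording, out_dir: str | Path) -> Path:
    """Write a recording as one TSV per wavelength plus a YAML header file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = list(rec.montage.names)
    for wi, wl in enumerate(rec.montage.wavelengths_nm):
        df = pd.DataFrame(rec.intensities[wi].T, columns=names)
        df.to_csv(out / _intensity_filename(wl), sep="\t", index=False,
                  float_format=_FLOAT_FMT)
    meta = {
        "subject_id": rec.subject_id,
        "fs_hz": float(rec.fs_hz),
        "wavelengths_nm": list(rec.montage.wavelengths_nm),
        "distance_mm": float(rec.montage.distance_mm),
        "channels": [
            {"source": s, "detector": d, "region": r}
            for (s, d), r in zip(rec.montage.channels, rec.montage.regions)
        ],
        "files": {str(wl): _intensity_filename(wl) for wl in rec.montage.wavelengths_nm},
    }
    (out / RECORDING_META).write_text(yaml.safe_dump(meta, sort_keys=True))
    return out


def read_recording(path: str | Path, dialect: str = "tsv") -> OpticalRecording:
    """Read a recording directory written by :func:`write_recording`.

    Only the ``tsv`` dialect is supported; the reader re-validates every
    invariant (positivity, matching shapes) before returning.
    """
    if dialect != "tsv":
        raise FormatError(f"unsupported recording dialect {dialect!r}")
    root = Path(path)
    meta_path = root / RECORDING_META
    if not meta_path.exists():
        raise FormatError(f"missing {RECORDING_META} in {root}")
    meta = yaml.safe_load(meta_path.read_text())
    try:
        wavelengths = tuple(int(w) for w in meta["wavelengths_nm"])
        channels = tuple((int(c["source"]), int(c["detector"])) for c in meta["channels"])
        regions = tuple(str(c["region"]) for c in meta["channels"])
        montage = Montage(channels, regions, float(meta.get("distance_mm", 30.0)),
                          wavelengths)
        fs = float(meta["fs_hz"])
        subject = str(meta["subject_id"])
        files = meta["files"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed {RECORDING_META}: {exc}") from exc

    planes = []
    for wl in wavelengths:
        fpath = root / files.get(str(wl), "")
        if not fpath.is_file():
            raise FormatError(f"missing intensity file for wavelength {wl} nm")
        df = pd.read_csv(fpath, sep="\t")
        expected = list(montage.names)
        if list(df.columns) != expected:
            raise FormatError(
                f"channel header of {fpath.name} does not match montage order"
            )
        planes.append(df.to_numpy(dtype=float).T)
    if planes[0].shape != planes[1].shape:
        raise FormatError("wavelength planes differ in shape")
    return OpticalRecording(np.stack(planes), fs, subject, montage)


def write_events(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated events table as TSV (BIDS-events-like columns)."""
    t = validate_trial_table(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t[EVENT_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no events file at {path}")
    table = pd.read_csv(path, sep="\t")
    return validate_trial_table(table)


def write_mood(scores: list[MoodScores], path: str | Path) -> Path:
    rows = []
    for s in scores:
        row = {"subject_id": s.subject_id, "timepoint": s.timepoint}
        row.update({f"item_{i + 1:02d}": v for i, v in enumerate(s.items)})
        rows.append(row)
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_mood(path: str | Path) -> list[MoodScores]:
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no mood file at {path}")
    df = pd.read_csv(path, sep="\t")
    item_cols = [c for c in df.columns if c.startswith("item_")]
    out = []
    for _, row in df.iterrows():
        out.append(MoodScores(str(row["subject_id"]), str(row["timepoint"]),
                              row[item_cols].to_numpy(dtype=float)))
    return out


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no feature table at {path}")
    df = pd.read_csv(path, sep="\t")
    feat_cols = [c for c in df.columns if c.endswith(("_HbO", "_HbR"))]
    if not feat_cols:
        raise FormatError("feature table has no *_HbO/*_HbR columns")
    if df[feat_cols].isna().any().any():
        raise ValidationError("feature table contains missing values")
    return df


def frame_to_tsv_string(df: pd.DataFrame) -> str:
    """Render a DataFrame to the exact TSV text the writers produce."""
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format=_FLOAT_FMT)
    return buf.getvalue()
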