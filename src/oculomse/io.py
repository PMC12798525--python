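"""Reading and writing of recordings, manifests and derived tables.

Recordings are vendor-neutral delimited text with a header row and the
columns ``time_s, gaze_h_deg, gaze_v_deg, pupil_left_mm, pupil_right_mm,
valid_left, valid_right``.  Every file written by the pipeline carries a
provenance header (comment lines with the config hash, seed and sampling
rate) so outputs are traceable to the configuration that produced them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import GazeRecording

__all__ = [
    "RECORDING_COLUMNS",
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
    "write_table",
    "read_table",
    "write_json_report",
    "read_feature_table",
]

RECORDING_COLUMNS = (
    "time_s",
    "gaze_h_deg",
    "gaze_v_deg",
    "pupil_left_mm",
    "pupil_right_mm",
    "valid_left",
    "valid_right",
)


def _provenance_lines(provenance: dict | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {key}={value}" for key, value in provenance.items()]


def _read_header_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def write_recording(
    recording: GazeRecording, path: str | Path, provenance: dict | None = None
) -> Path:
    """Write one recording as delimited text with a provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "time_s": recording.time,
            "gaze_h_deg": recording.gaze_h,
            "gaze_v_deg": recording.gaze_v,
            "pupil_left_mm": recording.pupil_l,
            "pupil_right_mm": recording.pupil_r,
            "valid_left": recording.valid_l.astype(int),
            "valid_right": recording.valid_r.astype(int),
        }
    )
    meta = {"participant_id": recording.participant_id, "fs_hz": repr(recording.fs_hz)}
    if provenance:
        meta.update(provenance)
    with open(path, "w") as fh:
        fh.write("\n".join(_provenance_lines(meta)) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_recording(path: str | Path, fs_hz: float | None = None) -> GazeRecording:
    """Read and validate a recording file.

    The sampling rate comes from the file's provenance header when present,
    from ``fs_hz`` when given, and otherwise from the median timestamp
    increment.  Raises a descriptive error on a malformed header, a
    missing column or non-uniform sampling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    meta = _read_header_meta(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {list(RECORDING_COLUMNS)}"
        )
    if fs_hz is None:
        if "fs_hz" in meta:
            fs_hz = float(meta["fs_hz"])
        else:
            dt = np.median(np.diff(df["time_s"].to_numpy()))
            if dt <= 0:
                raise ValueError(f"{path}: non-increasing timestamps")
            fs_hz = 1.0 / dt
    participant_id = meta.get("participant_id", path.stem)
    try:
        return GazeRecording(
            participant_id=participant_id,
            time=df["time_s"].to_numpy(),
            gaze_h=df["gaze_h_deg"].to_numpy(),
            gaze_v=df["gaze_v_deg"].to_numpy(),
            pupil_l=df["pupil_left_mm"].to_numpy(),
            pupil_r=df["pupil_right_mm"].to_numpy(),
            valid_l=df["valid_left"].to_numpy().astype(bool),
            valid_r=df["valid_right"].to_numpy().astype(bool),
            fs_hz=fs_hz,
        )
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


MANIFEST_COLUMNS = (
    "participant_id", "group", "drug_naive", "age_years", "sex",
    "asrs_total", "asrs_in", "asrs_hypi",
)


def write_manifest(
    manifest: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> Path:
    return write_table(manifest, path, provenance)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing column(s) {missing}")
    return df


def write_table(
    df: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> Path:
    """Write a DataFrame as CSV with an optional provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        lines = _provenance_lines(provenance)
        if lines:
            fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path, comment="#")


def write_json_report(obj: dict, path: str | Path, provenance: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if provenance:
        payload["provenance"] = provenance
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
    return path


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.bool_,)):
        return bool(value)
    raise TypeError(f"not JSON serializable: {type(value)}")


#: canonical feature-table columns and their roles
FEATURE_TABLE_COLUMNS = (
    "participant_id", "group", "drug_naive", "age_years", "sex",
    "asrs_total", "asrs_in", "asrs_hypi",
    "pupil_size", "hor_fuzzyen", "vert_fuzzyen",
)


def read_feature_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Import a participant-level feature table, optionally renaming columns.

    ``column_map`` maps external column names onto the canonical schema
    (e.g. ``{"Pupil Size": "pupil_size"}``), so externally deposited
    participant-level files with different headers can be adapted without
    code changes.
    """
    df = read_table(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: feature table missing column(s) {missing}; "
            "provide a column_map to adapt external headers"
        )
    return df
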