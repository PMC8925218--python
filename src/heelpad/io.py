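"""File formats: trial CSVs, cohort tables, geometry scenes, manifests.

Trial CSV schema (one file per heel-condition):

    # subject_id = S001
    # side = left
    # condition = time_zero
    # contact_index = 0
    frame,time_s,thickness_mm,force_N,area_cm2
    0,0.0,15.99,0.0,25.0
    ...

The ``#``-comment header carries trial metadata (unknown keys are ignored
on read); the column schema below it is fixed. Scenes are a directory with
a ``scene.json`` header (ball centers, radius, tilt, frame file names) and
one XYZ CSV per frame. All numbers are written with full precision via
``repr`` so a fixed-seed pipeline re-run is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .geometry import GeometryScene
from .mechanics import HeelProperties, TrialTimeSeries
from .stats import PROPERTY_NAMES, CohortRecord
from .synthetic import HeelParams

__all__ = [
    "write_trial_csv",
    "read_trial_csv",
    "write_params_csv",
    "read_params_csv",
    "write_properties_csv",
    "read_properties_csv",
    "records_from_properties",
    "write_scene",
    "read_scene",
    "write_loop_csv",
    "write_manifest",
]

TRIAL_COLUMNS = ["frame", "time_s", "thickness_mm", "force_N", "area_cm2"]
PROPERTIES_COLUMNS = ["subject_id", "side", "condition", "age", "bmi", *PROPERTY_NAMES]


def _fmt(x: float) -> str:
    return repr(float(x))


def write_trial_csv(ts: TrialTimeSeries, path: str | Path) -> None:
    path = Path(path)
    lines = []
    meta = dict(ts.meta)
    if ts.contact_index is not None:
        meta["contact_index"] = ts.contact_index
    for key in sorted(meta):
        lines.append(f"# {key} = {meta[key]}")
    lines.append(",".join(TRIAL_COLUMNS))
    for i in range(len(ts)):
        lines.append(
            f"{i},{_fmt(ts.time[i])},{_fmt(ts.thickness[i])},"
            f"{_fmt(ts.force[i])},{_fmt(ts.area[i])}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_trial_csv(path: str | Path) -> TrialTimeSeries:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing trial columns {missing}")
    contact = meta.pop("contact_index", None)
    return TrialTimeSeries(
        time=df["time_s"].to_numpy(float),
        thickness=df["thickness_mm"].to_numpy(float),
        force=df["force_N"].to_numpy(float),
        area=df["area_cm2"].to_numpy(float),
        contact_index=int(contact) if contact is not None else None,
        meta=meta,
    )


def write_params_csv(params: list[HeelParams], path: str | Path) -> None:
    pd.DataFrame([asdict(p) for p in params]).to_csv(path, index=False)


def read_params_csv(path: str | Path) -> list[HeelParams]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [HeelParams(**row) for row in df.to_dict(orient="records")]


def write_properties_csv(records: list[CohortRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "side": r.side,
            "condition": r.condition,
            "age": r.age,
            "bmi": r.bmi,
        }
        row.update(r.properties.as_dict())
        rows.append(row)
    pd.DataFrame(rows, columns=PROPERTIES_COLUMNS).to_csv(path, index=False)


def read_properties_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PROPERTIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing properties columns {missing}")
    return df


def records_from_properties(df: pd.DataFrame) -> list[CohortRecord]:
    """Rehydrate :class:`CohortRecord` objects from a properties table."""
    records = []
    for row in df.to_dict(orient="records"):
        props = HeelProperties(**{k: float(row[k]) for k in PROPERTY_NAMES})
        records.append(
            CohortRecord(
                subject_id=str(row["subject_id"]),
                side=str(row["side"]),
                condition=str(row["condition"]),
                age=float(row["age"]),
                bmi=float(row["bmi"]),
                properties=props,
            )
        )
    return records


def write_scene(scene: GeometryScene, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame_files = [f"frame_{i:04d}.csv" for i in range(len(scene.frames))]
    header = {
        "ball_centers": scene.ball_centers.tolist(),
        "ball_radius": scene.ball_radius,
        "plate_tilt_deg": scene.plate_tilt_deg,
        "frame_times_s": [t for t, _ in scene.frames],
        "frame_files": frame_files,
    }
    (directory / "scene.json").write_text(json.dumps(header, indent=1) + "\n")
    for fname, (_, cloud) in zip(frame_files, scene.frames):
        lines = ["x_mm,y_mm,z_mm"]
        for x, y, z in cloud:
            lines.append(f"{_fmt(x)},{_fmt(y)},{_fmt(z)}")
        (directory / fname).write_text("\n".join(lines) + "\n")


def read_scene(directory: str | Path) -> GeometryScene:
    directory = Path(directory)
    header_path = directory / "scene.json"
    if not header_path.exists():
        raise SchemaError(f"{directory}: no scene.json")
    header = json.loads(header_path.read_text())
    frames = []
    for t, fname in zip(header["frame_times_s"], header["frame_files"]):
        df = pd.read_csv(directory / fname, float_precision="round_trip")
        frames.append((float(t), df[["x_mm", "y_mm", "z_mm"]].to_numpy(float)))
    return GeometryScene(
        ball_centers=np.asarray(header["ball_centers"], dtype=float),
        ball_radius=float(header["ball_radius"]),
        frames=frames,
        plate_tilt_deg=float(header.get("plate_tilt_deg", 0.0)),
    )


def write_loop_csv(strain: np.ndarray, stress: np.ndarray, path: str | Path) -> None:
    """Two-column stress-strain loop for plotting."""
    lines = ["strain,stress_kpa"]
    for e, s in zip(strain, stress):
        lines.append(f"{_fmt(e)},{_fmt(s)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(directory: str | Path, out_name: str = "manifest.json") -> Path:
    """SHA-256 content hash of every file under `directory` (recursive)."""
    directory = Path(directory)
    entries = {}
    for f in sorted(directory.rglob("*")):
        if f.is_file() and f.name != out_name:
            entries[str(f.relative_to(directory))] = hashlib.sha256(
                f.read_bytes()
            ).hexdigest()
    out = directory / out_name
    out.write_text(json.dumps(entries, indent=1, sort_keys=True) + "\n")
    return out
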