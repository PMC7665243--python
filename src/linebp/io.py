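"""On-disk formats: trace CSV, cuff CSV, session manifests, report JSON.

Traces are plain CSV with a small metadata header::

    # channel=arterial
    # sample_rate_hz=1000.0
    # start_time_s=0.0
    time_s,pressure_mmhg
    0.000000,-151.23...

Uniform sampling is validated on read (max jitter 1e-9 s).  A session is a
directory with a ``session.yaml`` manifest naming the two trace CSVs, the
cuff CSV and the hardware configuration.  Simulated sessions additionally
carry a ``ground_truth.csv`` that the manifest deliberately does not
reference, so estimation commands cannot consume it by accident.  Files
ending in ``.gz`` are transparently compressed.
"""

from __future__ import annotations

import gzip
import io as _stdio
import json
from dataclasses import asdict
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .calibration import SessionCalibration
from .core import (
    CuffMeasurement,
    NeedleSpec,
    PressureTrace,
    PumpGeometry,
    SessionRecord,
    validate_session,
)
from .errors import FormatError
from .simulate import GroundTruth

MAX_JITTER_S = 1e-9


def _open_text(path: Path, mode: str):
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_trace_csv(trace: PressureTrace, path: Union[str, Path]) -> None:
    path = Path(path)
    times = trace.times()
    with _open_text(path, "w") as f:
        f.write(f"# channel={trace.channel}\n")
        f.write(f"# sample_rate_hz={trace.sample_rate_hz!r}\n")
        f.write(f"# start_time_s={trace.start_time!r}\n")
        f.write("time_s,pressure_mmhg\n")
        for t, v in zip(times, trace.values):
            f.write(f"{t:.6f},{float(v)!r}\n")


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with _open_text(path, "r") as f:
        for line in f:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_trace_csv(path: Union[str, Path]) -> PressureTrace:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trace file not found: {path}")
    meta = _read_metadata(path)
    for key in ("channel", "sample_rate_hz"):
        if key not in meta:
            raise FormatError(f"{path}: missing '# {key}=' metadata line")
    try:
        rate = float(meta["sample_rate_hz"])
    except ValueError:
        raise FormatError(f"{path}: sample_rate_hz is not numeric") from None
    with _open_text(path, "r") as f:
        df = pd.read_csv(f, comment="#", float_precision="round_trip")
    if list(df.columns) != ["time_s", "pressure_mmhg"]:
        raise FormatError(
            f"{path}: expected header 'time_s,pressure_mmhg', got {list(df.columns)}"
        )
    if len(df) == 0:
        raise FormatError(f"{path}: trace has no samples")
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) > 1:
        jitter = np.abs(np.diff(times) - 1.0 / rate)
        if float(jitter.max()) > MAX_JITTER_S + 1e-6 / rate:
            i = int(np.argmax(jitter))
            raise FormatError(
                f"{path}: non-uniform timestamps near row {i + 1} "
                f"(dt={times[i + 1] - times[i]:.9f} s, expected {1.0 / rate:.9f} s)"
            )
    start = float(meta.get("start_time_s", times[0]))
    return PressureTrace(
        values=df["pressure_mmhg"].to_numpy(dtype=float),
        sample_rate_hz=rate,
        start_time=start,
        channel=meta["channel"],  # type: ignore[arg-type]
    )


def write_cuffs_csv(cuffs: list[CuffMeasurement], path: Union[str, Path]) -> None:
    with _open_text(Path(path), "w") as f:
        f.write("time_s,systolic,diastolic,map\n")
        for c in cuffs:
            f.write(
                f"{c.time_s!r},{c.systolic_mmhg!r},{c.diastolic_mmhg!r},{c.map_mmhg!r}\n"
            )


def read_cuffs_csv(path: Union[str, Path]) -> list[CuffMeasurement]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cuff file not found: {path}")
    with _open_text(path, "r") as f:
        df = pd.read_csv(f, comment="#", float_precision="round_trip")
    expected = ["time_s", "systolic", "diastolic", "map"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected header {','.join(expected)}")
    return [
        CuffMeasurement(
            time_s=float(r.time_s),
            systolic_mmhg=float(r.systolic),
            diastolic_mmhg=float(r.diastolic),
            map_mmhg=float(r.map),
        )
        for r in df.itertuples()
    ]


def _needle_to_dict(n: NeedleSpec) -> dict:
    return {"gauge": n.gauge, "inner_diameter_mm": n.inner_diameter_mm}


def _needle_from_dict(d: dict) -> NeedleSpec:
    if "gauge" not in d:
        raise FormatError("needle spec requires a 'gauge' field")
    return NeedleSpec(int(d["gauge"]), d.get("inner_diameter_mm"))


def write_session(session: SessionRecord, directory: Union[str, Path]) -> Path:
    """Write a session directory; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_trace_csv(session.arterial, directory / "arterial.csv")
    write_trace_csv(session.venous, directory / "venous.csv")
    write_cuffs_csv(session.cuffs, directory / "cuffs.csv")
    manifest = {
        "session_id": session.session_id,
        "arterial_trace": "arterial.csv",
        "venous_trace": "venous.csv",
        "cuffs": "cuffs.csv",
        "arterial_needle": _needle_to_dict(session.arterial_needle),
        "venous_needle": _needle_to_dict(session.venous_needle),
        "pump": {
            "line_radius_mm": session.pump.line_radius_mm,
            "effective_length_mm": session.pump.effective_length_mm,
            "lobe_count": session.pump.lobe_count,
        },
        "set_flow_ml_min": session.set_flow_ml_min,
    }
    path = directory / "session.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def read_session(path: Union[str, Path]) -> SessionRecord:
    """Read a session from a manifest file or a directory containing one."""
    path = Path(path)
    manifest_path = path / "session.yaml" if path.is_dir() else path
    if not manifest_path.exists():
        raise FormatError(f"session manifest not found: {manifest_path}")
    try:
        manifest = yaml.safe_load(manifest_path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{manifest_path}: invalid YAML: {exc}") from None
    if not isinstance(manifest, dict):
        raise FormatError(f"{manifest_path}: manifest must be a mapping")
    base = manifest_path.parent
    for key in ("arterial_trace", "venous_trace", "cuffs"):
        if key not in manifest:
            raise FormatError(f"{manifest_path}: missing '{key}'")
        if not (base / manifest[key]).exists():
            raise FormatError(
                f"{manifest_path}: referenced file missing: {manifest[key]}"
            )
    pump_d = manifest.get("pump", {})
    session = SessionRecord(
        arterial=read_trace_csv(base / manifest["arterial_trace"]),
        venous=read_trace_csv(base / manifest["venous_trace"]),
        cuffs=read_cuffs_csv(base / manifest["cuffs"]),
        arterial_needle=_needle_from_dict(manifest.get("arterial_needle", {"gauge": 14})),
        venous_needle=_needle_from_dict(manifest.get("venous_needle", {"gauge": 14})),
        pump=PumpGeometry(
            line_radius_mm=float(pump_d.get("line_radius_mm", 4.0)),
            effective_length_mm=float(pump_d.get("effective_length_mm", 107.8)),
            lobe_count=int(pump_d.get("lobe_count", 2)),
        ),
        set_flow_ml_min=manifest.get("set_flow_ml_min"),
        session_id=str(manifest.get("session_id", manifest_path.parent.name)),
    )
    import logging

    for finding in validate_session(session):
        logging.getLogger(__name__).log(
            logging.ERROR if finding.severity == "error" else logging.WARNING,
            "%s: %s", finding.code, finding.message,
        )
    return session


def write_ground_truth(truth: GroundTruth, directory: Union[str, Path]) -> Path:
    """Write ground truth beside a simulated session (never in the manifest)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "ground_truth.csv"
    buf = _stdio.StringIO()
    buf.write(f"# pump_start_s={truth.pump_start_s!r}\n")
    pd.DataFrame(
        {
            "time_s": truth.times_s,
            "flow_ml_min": truth.flow_ml_min,
            "c_value": truth.c_value,
            "map_mmhg": truth.map_mmhg,
        }
    ).to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    return path


def read_ground_truth(directory: Union[str, Path]) -> GroundTruth:
    path = Path(directory) / "ground_truth.csv"
    if not path.exists():
        raise FormatError(f"ground truth not found: {path}")
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return GroundTruth(
        times_s=df["time_s"].to_numpy(float),
        flow_ml_min=df["flow_ml_min"].to_numpy(float),
        c_value=df["c_value"].to_numpy(float),
        map_mmhg=df["map_mmhg"].to_numpy(float),
        pump_start_s=float(meta.get("pump_start_s", 0.0)),
    )


def calibration_to_dict(cal: SessionCalibration) -> dict:
    d = {
        "session_id": cal.session_id,
        "gauge_label": cal.gauge_label,
        "c_session": cal.c_session,
        "c_sd": cal.c_sd,
        "c_min": cal.c_min,
        "c_max": cal.c_max,
        "points": [asdict(p) for p in cal.points],
        "skipped": [{"time_s": t, "reason": r} for t, r in cal.skipped],
    }
    return d


def write_json(obj: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
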