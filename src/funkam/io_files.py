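"""Readers/writers for motion-capture text formats and model serialization.

TRC carries marker trajectories (mm or m; metres in memory), MOT/STO carry
force-plate wrenches, coordinates and moments (tab-delimited with an
``endheader`` block; angles are written in degrees and stored in radians).
Models and calibrations serialize to versioned JSON/YAML documents.  All
writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import FunctionalCalibration, JointFrame
from .dynamics import MomentSeries, WrenchSeries
from .errors import ValidationError
from .ik import CoordinateTrajectory
from .markers import CommonShape, MarkerTrajectorySet
from .model import Coordinate, Joint, Model, Segment
from .rigid import RigidTransform

log = logging.getLogger("funkam.io")

SCHEMA_VERSION = 1

__all__ = [
    "read_trc",
    "write_trc",
    "read_mot",
    "write_mot",
    "write_sto_coordinates",
    "write_sto_moments",
    "save_model",
    "load_model",
    "save_calibration",
    "load_calibration",
    "atomic_write_text",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------


def write_trc(trial: MarkerTrajectorySet, path: str | Path, units: str = "mm") -> None:
    if units not in ("mm", "m"):
        raise ValidationError("TRC units must be 'mm' or 'm'")
    scale = 1000.0 if units == "mm" else 1.0
    nf, nm = trial.positions.shape[:2]
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{Path(path).name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{trial.rate:g}\t{trial.rate:g}\t{nf}\t{nm}\t{units}\t{trial.rate:g}\t1\t{nf}",
        "Frame#\tTime\t" + "\t\t\t".join(trial.labels) + "\t\t",
        "\t\t" + "\t".join(f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(nm)),
        "",
    ]
    for f in range(nf):
        cells = [str(f + 1), f"{trial.times[f]:.6f}"]
        for m in range(nm):
            if trial.occluded[f, m]:
                cells.extend(["", "", ""])
            else:
                cells.extend(f"{v * scale:.6f}" for v in trial.positions[f, m])
        lines.append("\t".join(cells))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_trc(path: str | Path) -> MarkerTrajectorySet:
    path = Path(path)
    raw = path.read_text().splitlines()
    try:
        header_vals = raw[2].split("\t")
        rate = float(header_vals[0])
        units = header_vals[4].strip()
        label_row = raw[3].split("\t")
    except (IndexError, ValueError) as exc:
        raise ValidationError(f"{path}: malformed TRC header (lines 1-4): {exc}") from None
    if units not in ("mm", "m"):
        raise ValidationError(f"{path}: line 3: unsupported units {units!r}")
    scale = 1e-3 if units == "mm" else 1.0
    labels = [c.strip() for c in label_row[2:] if c.strip()]
    nm = len(labels)
    positions = []
    occluded = []
    times = []
    for ln, line in enumerate(raw[5:], start=6):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < 2 + 3 * nm:
            cells = cells + [""] * (2 + 3 * nm - len(cells))
        try:
            times.append(float(cells[1]))
            row = np.full((nm, 3), np.nan)
            occ = np.zeros(nm, dtype=bool)
            for m in range(nm):
                trip = cells[2 + 3 * m : 5 + 3 * m]
                if any(c.strip() == "" for c in trip):
                    occ[m] = True
                else:
                    row[m] = [float(c) * scale for c in trip]
            positions.append(row)
            occluded.append(occ)
        except ValueError as exc:
            raise ValidationError(f"{path}: line {ln}: {exc}") from None
    pos = np.asarray(positions)
    pos[np.asarray(occluded)] = 0.0
    return MarkerTrajectorySet(labels, rate, pos, np.asarray(occluded), np.asarray(times))


# ---------------------------------------------------------------------------
# MOT / STO
# ---------------------------------------------------------------------------


def _write_sto(path: str | Path, name: str, columns: list[str], data: np.ndarray, in_degrees: bool) -> None:
    lines = [
        name,
        "version=1",
        f"nRows={data.shape[0]}",
        f"nColumns={data.shape[1]}",
        f"inDegrees={'yes' if in_degrees else 'no'}",
        "endheader",
        "\t".join(columns),
    ]
    for row in data:
        lines.append("\t".join(f"{v:.8g}" for v in row))
    atomic_write_text(path, "\n".join(lines) + "\n")


def _read_sto(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    raw = path.read_text().splitlines()
    try:
        end = next(i for i, l in enumerate(raw) if l.strip().lower() == "endheader")
    except StopIteration:
        raise ValidationError(f"{path}: no endheader line") from None
    cols = raw[end + 1].split("\t")
    rows = [
        [float(c) for c in line.split("\t")]
        for line in raw[end + 2 :]
        if line.strip()
    ]
    return pd.DataFrame(rows, columns=[c.strip() for c in cols])


WRENCH_COLUMNS = [
    "time",
    "ground_force_vx",
    "ground_force_vy",
    "ground_force_vz",
    "ground_force_px",
    "ground_force_py",
    "ground_force_pz",
    "ground_torque_x",
    "ground_torque_y",
    "ground_torque_z",
]


def write_mot(ws: WrenchSeries, path: str | Path) -> None:
    data = np.column_stack([ws.times, ws.force, ws.application_point, ws.moment])
    _write_sto(path, Path(path).stem, WRENCH_COLUMNS, data, in_degrees=False)


def read_mot(path: str | Path) -> WrenchSeries:
    df = _read_sto(path)
    if "time" not in df.columns:
        raise ValidationError(f"{path}: missing time column")
    t = df["time"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValidationError(f"{path}: non-monotone time column")

    def block(prefix_list):
        return np.column_stack([df[c].to_numpy() for c in prefix_list])

    force = block(["ground_force_vx", "ground_force_vy", "ground_force_vz"])
    moment_cols = ["ground_torque_x", "ground_torque_y", "ground_torque_z"]
    moment = (
        block(moment_cols)
        if all(c in df.columns for c in moment_cols)
        else np.zeros_like(force)
    )
    cop_cols = ["ground_force_px", "ground_force_py", "ground_force_pz"]
    if all(c in df.columns for c in cop_cols):
        cop = block(cop_cols)
    else:
        # center of pressure from the wrench about the origin, on the y=0
        # plane: p x F + couple_y = M  =>  px = Mz/Fy, pz = -Mx/Fy
        log.info("%s: COP columns missing; computing from wrench", path)
        fy = np.where(np.abs(force[:, 1]) > 1e-9, force[:, 1], np.nan)
        cop = np.zeros_like(force)
        cop[:, 0] = np.nan_to_num(moment[:, 2] / fy)
        cop[:, 2] = np.nan_to_num(-moment[:, 0] / fy)
        moment = moment.copy()
        moment[:, 0] = 0.0
        moment[:, 2] = 0.0
        moment[:, 1] -= cop[:, 2] * force[:, 0] - cop[:, 0] * force[:, 2]
    return WrenchSeries(t, force, moment, cop)


def write_sto_coordinates(traj: CoordinateTrajectory, path: str | Path, model: Model | None = None) -> None:
    """Coordinate series as STO; rotational coordinates in degrees."""
    if model is None:
        rot = set(traj.names)
    else:
        rot = {c.name for j in model.joints for c in j.coordinates if c.kind == "rot"}
    data = traj.q.copy()
    for i, name in enumerate(traj.names):
        if name in rot:
            data[:, i] = np.degrees(data[:, i])
    out = np.column_stack([traj.times, data])
    _write_sto(path, Path(path).stem, ["time"] + list(traj.names), out, in_degrees=True)


def write_sto_moments(ms: MomentSeries, path: str | Path) -> None:
    cols = ["time", "knee_adduction_moment"] + list(ms.sagittal)
    data = np.column_stack([ms.times, ms.eam] + [ms.sagittal[k] for k in ms.sagittal])
    _write_sto(path, f"{Path(path).stem} ({ms.units})", cols, data, in_degrees=False)


def read_sto_series(path: str | Path) -> pd.DataFrame:
    """Generic STO reader returning a time-indexed data frame."""
    return _read_sto(path)


# ---------------------------------------------------------------------------
# model / calibration serialization
# ---------------------------------------------------------------------------


def _arr(x) -> list:
    return np.asarray(x, dtype=float).tolist()


def _model_to_dict(model: Model) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "funkam-model",
        "gravity": _arr(model.gravity),
        "segments": {
            s.name: {
                "mass": s.mass,
                "com": _arr(s.com),
                "inertia": _arr(s.inertia),
                "markers": {k: _arr(v) for k, v in s.local_markers.items()},
            }
            for s in model.segments.values()
        },
        "joints": [
            {
                "name": j.name,
                "parent": j.parent,
                "child": j.child,
                "parent_placement": {"R": _arr(j.parent_placement.rotation), "t": _arr(j.parent_placement.translation)},
                "child_placement": {"R": _arr(j.child_placement.rotation), "t": _arr(j.child_placement.translation)},
                "coordinates": [
                    {"name": c.name, "kind": c.kind, "axis": _arr(c.axis)} for c in j.coordinates
                ],
                "coupling": None
                if j.coupling is None
                else {"angles": _arr(j.coupling[0]), "offsets": _arr(j.coupling[1])},
            }
            for j in model.joints
        ],
    }


def _model_from_dict(doc: dict) -> Model:
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported model schema version {doc.get('schema_version')!r}; "
            f"expected {SCHEMA_VERSION} (no migration available)"
        )
    segments = {
        name: Segment(name, d["mass"], np.array(d["com"]), np.array(d["inertia"]),
                      {k: np.array(v) for k, v in d["markers"].items()})
        for name, d in doc["segments"].items()
    }
    joints = []
    for jd in doc["joints"]:
        joints.append(
            Joint(
                jd["name"],
                jd["parent"],
                jd["child"],
                RigidTransform(np.array(jd["parent_placement"]["R"]), np.array(jd["parent_placement"]["t"])),
                RigidTransform(np.array(jd["child_placement"]["R"]), np.array(jd["child_placement"]["t"])),
                [Coordinate(c["name"], c["kind"], np.array(c["axis"])) for c in jd["coordinates"]],
                None
                if jd.get("coupling") is None
                else (np.array(jd["coupling"]["angles"]), np.array(jd["coupling"]["offsets"])),
            )
        )
    return Model(segments, joints, np.array(doc["gravity"]))


def _dump(doc: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        atomic_write_text(path, yaml.safe_dump(doc, sort_keys=True))
    else:
        atomic_write_text(path, json.dumps(doc, indent=1, sort_keys=True))


def _load(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_model(model: Model, path: str | Path) -> None:
    _dump(_model_to_dict(model), path)


def load_model(path: str | Path) -> Model:
    return _model_from_dict(_load(path))


def _jf_to_dict(jf: JointFrame) -> dict:
    return {"origin": _arr(jf.origin), "axes": _arr(jf.axes), "expressed_in": jf.expressed_in}


def _jf_from_dict(d: dict) -> JointFrame:
    return JointFrame(np.array(d["origin"]), np.array(d["axes"]), d["expressed_in"])


def save_calibration(cal: FunctionalCalibration, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": "funkam-calibration",
        "shapes": {
            c: {"labels": list(s.labels), "local_positions": _arr(s.local_positions), "rms": s.rms_residual}
            for c, s in cal.shapes.items()
        },
        "hjc_in_pelvis": _arr(cal.hjc_in_pelvis),
        "hjc_in_thigh": _arr(cal.hjc_in_thigh),
        "knee_axis": {c: {"point": _arr(p), "dir": _arr(d)} for c, (p, d) in cal.knee_axis.items()},
        "ankle_axis": {c: {"point": _arr(p), "dir": _arr(d)} for c, (p, d) in cal.ankle_axis.items()},
        "kjc_local": {c: _arr(p) for c, p in cal.kjc_local.items()},
        "ajc_local": {c: _arr(p) for c, p in cal.ajc_local.items()},
        "jcs_knee_local": {c: _jf_to_dict(f) for c, f in cal.jcs_knee_local.items()},
        "jcs_ankle_local": {c: _jf_to_dict(f) for c, f in cal.jcs_ankle_local.items()},
        "kjc": _arr(cal.kjc),
        "ajc": _arr(cal.ajc),
        "hjc": _arr(cal.hjc),
        "jcs_knee": _jf_to_dict(cal.jcs_knee),
        "jcs_ankle": _jf_to_dict(cal.jcs_ankle),
        "pelvis_axes_local": _arr(cal.pelvis_axes_local),
        "anatomic_axes_local": {c: _arr(a) for c, a in cal.anatomic_axes_local.items()},
        "residuals": json.loads(json.dumps(cal.residuals)),
    }
    _dump(doc, path)


def load_calibration(path: str | Path) -> FunctionalCalibration:
    doc = _load(path)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported calibration schema version {doc.get('schema_version')!r}"
        )
    shapes = {
        c: CommonShape(d["labels"], np.array(d["local_positions"]), [], d["rms"])
        for c, d in doc["shapes"].items()
    }
    return FunctionalCalibration(
        shapes=shapes,
        hjc_in_pelvis=np.array(doc["hjc_in_pelvis"]),
        hjc_in_thigh=np.array(doc["hjc_in_thigh"]),
        knee_axis={c: (np.array(d["point"]), np.array(d["dir"])) for c, d in doc["knee_axis"].items()},
        ankle_axis={c: (np.array(d["point"]), np.array(d["dir"])) for c, d in doc["ankle_axis"].items()},
        kjc_local={c: np.array(p) for c, p in doc["kjc_local"].items()},
        ajc_local={c: np.array(p) for c, p in doc["ajc_local"].items()},
        jcs_knee_local={c: _jf_from_dict(d) for c, d in doc["jcs_knee_local"].items()},
        jcs_ankle_local={c: _jf_from_dict(d) for c, d in doc["jcs_ankle_local"].items()},
        kjc=np.array(doc["kjc"]),
        ajc=np.array(doc["ajc"]),
        hjc=np.array(doc["hjc"]),
        jcs_knee=_jf_from_dict(doc["jcs_knee"]),
        jcs_ankle=_jf_from_dict(doc["jcs_ankle"]),
        pelvis_axes_local=np.array(doc["pelvis_axes_local"]),
        anatomic_axes_local={c: np.array(a) for c, a in doc.get("anatomic_axes_local", {}).items()},
        residuals=doc.get("residuals", {}),
    )
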