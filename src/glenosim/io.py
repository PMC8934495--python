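"""Model-config (YAML), motion/marker CSV and results I/O.

File interfaces use the source conventions — lengths in millimetres,
angles in degrees, masses in kilograms — and are converted to SI
(metres, radians) on load.  Floats are written at 9 significant digits
so write∘read round-trips up to formatting.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd
import yaml

from .chain import BodySegment, ChainModel, JointSpec
from .geometry import Frame
from .motions import MarkerSet, QSeries
from .muscles import MuscleElement
from .wrapping import MusclePathSpec, WrapSurface

MM = 1000.0


def _fmt(x) -> float:
    return float(f"{float(x):.9g}")


def _vec_mm(v) -> List[float]:
    return [_fmt(x * MM) for x in np.asarray(v, float)]


def _vec_from_mm(v) -> np.ndarray:
    return np.asarray(v, float) / MM


def _frame_to_dict(f: Frame) -> dict:
    from scipy.spatial.transform import Rotation
    rv = Rotation.from_matrix(f.rotation).as_rotvec(degrees=True)
    return {"rotvec_deg": [_fmt(x) for x in rv], "translation_mm": _vec_mm(f.translation)}


def _frame_from_dict(d: dict) -> Frame:
    from scipy.spatial.transform import Rotation
    rot = Rotation.from_rotvec(np.asarray(d.get("rotvec_deg", [0, 0, 0]), float),
                               degrees=True).as_matrix()
    return Frame(rot, _vec_from_mm(d.get("translation_mm", [0, 0, 0])))


def model_to_dict(model: ChainModel) -> dict:
    return {
        "name": model.name,
        "gravity_m_s2": [_fmt(x) for x in model.gravity],
        "gh_joint": model.gh_joint_name,
        "gh_coords": list(model.gh_coord_names),
        "bodies": [{
            "name": b.name, "mass_kg": _fmt(b.mass),
            "com_mm": _vec_mm(b.com_local),
            "point_loads": [{"point_mm": _vec_mm(p), "mass_kg": _fmt(m)}
                            for p, m in b.attached_point_loads],
        } for b in model.bodies.values()],
        "joints": [{
            "name": j.name, "kind": j.kind,
            "parent": j.parent_body, "child": j.child_body,
            "parent_offset": _frame_to_dict(j.parent_frame_offset),
            "child_offset": _frame_to_dict(j.child_frame_offset),
            "axes": [[_fmt(x) for x in a] for a in j.axes],
            "coords": list(j.coord_names), "driven": bool(j.driven),
        } for j in model.joints],
        "wraps": [{
            "name": w.name, "kind": w.kind, "body": w.body,
            "center_mm": _vec_mm(w.center_local),
            "radii_mm": _vec_mm(w.radii),
            "orientation": _frame_to_dict(Frame(w.orientation_local)),
            "active_muscles": list(w.active_muscles),
        } for w in model.wraps.values()],
        "muscles": [{
            "name": m.name, "group": m.group, "f_max_n": _fmt(m.f_max),
            "l_opt_mm": _fmt(m.l_opt * MM), "l_slack_mm": _fmt(m.l_slack * MM),
            "active": bool(m.active),
            "origin": {"body": m.path.origin[0], "point_mm": _vec_mm(m.path.origin[1])},
            "insertion": {"body": m.path.insertion[0], "point_mm": _vec_mm(m.path.insertion[1])},
            "via_points": [{"body": b, "point_mm": _vec_mm(p)} for b, p in m.path.via_points],
            "wraps": list(m.path.wrap_assignments),
        } for m in model.muscles],
    }


class SchemaError(ValueError):
    pass


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise SchemaError(f"{where}: missing required field {key!r}")
    return d[key]


def model_from_dict(d: dict) -> ChainModel:
    bodies = []
    for bd in _require(d, "bodies", "model"):
        bodies.append(BodySegment(
            _require(bd, "name", "body"), float(bd.get("mass_kg", 0.0)),
            _vec_from_mm(bd.get("com_mm", [0, 0, 0])),
            [( _vec_from_mm(_require(pl, "point_mm", "point_load")), float(pl["mass_kg"]))
             for pl in bd.get("point_loads", [])]))
    joints = []
    for jd in _require(d, "joints", "model"):
        kind = _require(jd, "kind", f"joint {jd.get('name')}")
        try:
            joints.append(JointSpec(
                _require(jd, "name", "joint"), kind,
                _require(jd, "parent", "joint"), _require(jd, "child", "joint"),
                _frame_from_dict(jd.get("parent_offset", {})),
                _frame_from_dict(jd.get("child_offset", {})),
                [np.asarray(a, float) for a in jd.get("axes", [])],
                jd.get("coords"), bool(jd.get("driven", False))))
        except ValueError as e:
            raise SchemaError(f"joint {jd.get('name')}: {e}") from e
    wraps = {}
    for wd in d.get("wraps", []):
        w = WrapSurface(_require(wd, "name", "wrap"), _require(wd, "kind", "wrap"),
                        _require(wd, "body", "wrap"),
                        _vec_from_mm(wd.get("center_mm", [0, 0, 0])),
                        _vec_from_mm(_require(wd, "radii_mm", "wrap")),
                        _frame_from_dict(wd.get("orientation", {})).rotation,
                        list(wd.get("active_muscles", [])))
        wraps[w.name] = w
    muscles = []
    for md in d.get("muscles", []):
        path = MusclePathSpec(
            (md["origin"]["body"], _vec_from_mm(md["origin"]["point_mm"])),
            (md["insertion"]["body"], _vec_from_mm(md["insertion"]["point_mm"])),
            [(v["body"], _vec_from_mm(v["point_mm"])) for v in md.get("via_points", [])],
            list(md.get("wraps", [])))
        muscles.append(MuscleElement(
            _require(md, "name", "muscle"), md.get("group", "other"),
            float(_require(md, "f_max_n", "muscle")),
            float(md.get("l_opt_mm", 100.0)) / MM,
            float(md.get("l_slack_mm", 0.0)) / MM, path,
            bool(md.get("active", True))))
    return ChainModel(bodies, joints, muscles, wraps,
                      gravity=np.asarray(d.get("gravity_m_s2", [0, -9.81, 0]), float),
                      gh_joint_name=d.get("gh_joint"), name=d.get("name", "model"),
                      gh_coord_names=list(d.get("gh_coords", [])))


def write_model(model: ChainModel, path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))


def read_model(path) -> ChainModel:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# series / marker / results CSV


def write_motion_csv(series: QSeries, path) -> None:
    rows = []
    for i, t in enumerate(series.times):
        for j, name in enumerate(series.coord_names):
            rows.append({"time_s": _fmt(t), "dof": name,
                         "angle_deg": _fmt(np.rad2deg(series.values[i, j]))})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_motion_csv(path) -> QSeries:
    df = pd.read_csv(path)
    names = list(dict.fromkeys(df["dof"]))
    times = np.array(sorted(df["time_s"].unique()))
    values = np.zeros((len(times), len(names)))
    tindex = {t: i for i, t in enumerate(times)}
    nindex = {n: j for j, n in enumerate(names)}
    for _, r in df.iterrows():
        values[tindex[r.time_s], nindex[r.dof]] = np.deg2rad(r.angle_deg)
    return QSeries(times, values, names)


def write_marker_csv(markers: MarkerSet, path) -> None:
    rows = []
    for name, _, _ in markers.markers:
        for i, t in enumerate(markers.times):
            x, y, z = markers.trajectories[name][i]
            rows.append({"time_s": _fmt(t), "marker": name,
                         "x_m": _fmt(x), "y_m": _fmt(y), "z_m": _fmt(z)})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_motion_result(result, out_dir) -> Dict[str, Path]:
    """forces.csv, activations.csv, jrf.csv, reserves.csv under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = {"time_s": result.times}
    paths = {}
    force_rows = []
    for i, t in enumerate(result.times):
        for j, name in enumerate(result.element_names):
            if not result.element_active[name]:
                continue
            force_rows.append({"time_s": _fmt(t), "element": name,
                               "group": result.element_groups[name],
                               "activation": _fmt(result.activations[i, j]),
                               "force_N": _fmt(result.forces[i, j])})
    paths["forces"] = out / "forces.csv"
    pd.DataFrame(force_rows).to_csv(paths["forces"], index=False)
    act = pd.DataFrame(result.activations,
                       columns=result.element_names).assign(**base)
    paths["activations"] = out / "activations.csv"
    act.to_csv(paths["activations"], index=False)
    jrf = pd.DataFrame({"time_s": result.times,
                        "jrf_x_N": result.jrf_world[:, 0],
                        "jrf_y_N": result.jrf_world[:, 1],
                        "jrf_z_N": result.jrf_world[:, 2],
                        "jrf_N": result.jrf_magnitude,
                        "status": result.statuses})
    paths["jrf"] = out / "jrf.csv"
    jrf.to_csv(paths["jrf"], index=False)
    res = pd.DataFrame(result.reserves).assign(**base)
    paths["reserves"] = out / "reserves.csv"
    res.to_csv(paths["reserves"], index=False)
    return paths


def write_manifest(out_dir, entries: dict) -> Path:
    """Reproducibility manifest: inputs, seeds, versions, checksums."""
    import glenosim
    out = Path(out_dir)
    manifest = {"package_version": glenosim.__version__, **entries, "checksums": {}}
    for p in sorted(out.glob("*.csv")):
        manifest["checksums"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
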