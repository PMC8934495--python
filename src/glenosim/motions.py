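"""Motion trajectory generation, synthetic marker capture, marker-based
inverse kinematics and the quasi-static time-stretch treatment.

Four protocol motions are supported: abduction (coronal elevation
0–120°), scaption (elevation in a plane 30° anterior to coronal,
0–120°), internal rotation (0–40° about the humeral long axis) and
external rotation (40°–0° by default).  Driven coordinates follow a
minimum-jerk profile (zero end-point velocity — the motions start and
stop at rest).  Elevation motions optionally carry a simplified 2:1
scapulohumeral rhythm (gleno-humeral : scapular upward rotation) above
30° of elevation.

The synthetic marker stage emulates a surface-marker capture: world
landmark positions from forward kinematics plus i.i.d. Gaussian noise
per axis, deterministic for a given seed.  Inverse kinematics solves
per-frame nonlinear least squares on the marker residuals
(Gauss–Newton on the point Jacobian, warm-started from the previous
frame).  ``time_stretch`` multiplies the time base by a constant factor
(default 1000), shrinking implied accelerations by the factor squared —
the treatment that renders a noisy capture quasi-static without
filtering the marker data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .chain import ChainModel, Configuration
from .geometry import Frame
from .implants import GH_COORDS, SCAPULA_COORD

MOTION_NAMES = ("ABD", "SCP", "IR", "ER")
SCAPTION_PLANE_DEG = 30.0  # anterior to coronal
DEFAULT_TIME_STRETCH = 1000.0
QUASI_STATIC_ACC_LIMIT = 1e-3  # rad/s^2

#: elbow posture per motion (deg); rotations use the clinical 90° flexed
#: posture, elevation motions the extended arm
ELBOW_FLEXION_DEG = {"ABD": 0.0, "SCP": 0.0, "IR": 90.0, "ER": 90.0}

_MOTION_RANGES = {"ABD": (0.0, 120.0), "SCP": (0.0, 120.0),
                  "IR": (0.0, 40.0), "ER": (40.0, 0.0)}


@dataclass
class MotionSpec:
    """One protocol motion."""

    name: str
    angle_start: float = None  # degrees
    angle_end: float = None
    n_steps: int = 25
    duration: float = 4.0      # seconds (before any time stretch)
    scapular_rhythm: bool = True
    er_reversed: bool = True   # ER runs 40°→0° by default

    def __post_init__(self) -> None:
        if self.name not in MOTION_NAMES:
            raise ValueError(f"unknown motion {self.name!r}; expected one of {MOTION_NAMES}")
        lo, hi = _MOTION_RANGES[self.name]
        if self.name == "ER" and not self.er_reversed:
            lo, hi = hi, lo
        if self.angle_start is None:
            self.angle_start = lo
        if self.angle_end is None:
            self.angle_end = hi
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")

    @property
    def timestamps(self) -> np.ndarray:
        return np.linspace(0.0, self.duration, self.n_steps)


@dataclass
class QSeries:
    """A timed series of generalized coordinates (radians)."""

    times: np.ndarray
    values: np.ndarray           # n_steps × DOF
    coord_names: List[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def configuration(self, i: int) -> Configuration:
        return Configuration(self.values[i])


@dataclass
class MarkerSet:
    """Named surface markers with per-frame world trajectories."""

    markers: List[Tuple[str, str, np.ndarray]]   # (name, body, point_local)
    trajectories: Dict[str, np.ndarray]          # name -> n_frames × 3, m
    times: np.ndarray
    rate: float = 100.0

    def __post_init__(self) -> None:
        lengths = {len(t) for t in self.trajectories.values()}
        if len(lengths) > 1:
            raise ValueError("marker trajectories must have equal length")


def minimum_jerk(s: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on s ∈ [0, 1]
    (zero velocity and acceleration at both ends)."""
    s = np.asarray(s, float)
    return 10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5


def _desired_gh_rotation(name: str, angle_rad: float) -> Rotation:
    """Humerus orientation relative to the scapula for one motion angle.

    Abduction elevates about the −x (posterior-viewed coronal) axis,
    scaption about that axis swung 30° anterior, and the rotations spin
    the humeral long axis (internal positive)."""
    if name == "ABD":
        axis = np.array([-1.0, 0.0, 0.0])
    elif name == "SCP":
        a = np.deg2rad(SCAPTION_PLANE_DEG)
        axis = np.array([-np.cos(a), 0.0, np.sin(a)])
    elif name in ("IR", "ER"):
        axis = np.array([0.0, 1.0, 0.0])
        if name == "ER":
            angle_rad = -angle_rad  # external = negative internal rotation
    else:
        raise ValueError(name)
    return Rotation.from_rotvec(axis * angle_rad)


def _gh_rotation_of(model: ChainModel, gh_q: np.ndarray) -> Rotation:
    """Humerus orientation relative to scapula at the given GH coordinates."""
    q = np.zeros(model.n_dof)
    for name, val in zip(GH_COORDS, gh_q):
        q[model.coord_index(name)] = val
    frames = model.forward_kinematics(q)
    r = frames["scapula"].rotation.T @ frames["humerus"].rotation
    return Rotation.from_matrix(r)


def solve_gh_angles(model: ChainModel, target: Rotation,
                    x0: Optional[np.ndarray] = None) -> np.ndarray:
    """Invert the model's GH parameterization for a target humerus
    orientation (3-angle nonlinear least squares, warm-startable)."""

    def residual(x):
        return (_gh_rotation_of(model, x).inv() * target).as_rotvec()

    res = least_squares(residual, np.zeros(3) if x0 is None else np.asarray(x0, float),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return res.x


def generate_trajectory(model: ChainModel, spec: MotionSpec) -> QSeries:
    """Joint-coordinate time series realizing a protocol motion on a
    given shoulder model (minimum-jerk ramp on the driven angle)."""
    s = minimum_jerk(np.linspace(0.0, 1.0, spec.n_steps))
    angles = np.deg2rad(spec.angle_start + (spec.angle_end - spec.angle_start) * s)
    values = np.zeros((spec.n_steps, model.n_dof))
    gh_idx = [model.coord_index(c) for c in GH_COORDS]
    warm = np.zeros(3)
    for i, ang in enumerate(angles):
        target = _desired_gh_rotation(spec.name, ang)
        gh = solve_gh_angles(model, target, warm)
        warm = gh
        values[i, gh_idx] = gh
        if spec.scapular_rhythm and spec.name in ("ABD", "SCP"):
            elev_deg = np.rad2deg(ang)
            values[i, model.coord_index(SCAPULA_COORD)] = np.deg2rad(
                max(0.0, elev_deg - 30.0) / 2.0)
    return QSeries(spec.timestamps, values, list(model.coord_names))


# ---------------------------------------------------------------------------
# markers


def default_marker_set(model: ChainModel) -> List[Tuple[str, str, np.ndarray]]:
    """Anatomical-landmark-style marker placement (synthetic)."""
    markers = [
        ("sternum", "thorax", (0.050, 0.000, 0.000)),
        ("c7", "thorax", (-0.040, 0.060, 0.000)),
        ("xiphoid", "thorax", (0.055, -0.120, 0.000)),
        ("acromion", "scapula", (0.000, 0.012, 0.005)),
        ("scapula_spine", "scapula", (-0.070, -0.010, -0.060)),
        ("inferior_angle", "scapula", (-0.050, -0.120, -0.050)),
        ("deltoid_tuberosity", "humerus", (0.012, -0.150, 0.018)),
        ("lateral_epicondyle", "humerus", (0.000, -0.300, 0.030)),
        ("medial_epicondyle", "humerus", (0.000, -0.300, -0.030)),
        ("radial_styloid", "radius", (0.012, -0.220, 0.015)),
        ("hand_dorsum", "hand", (0.010, -0.050, 0.008)),
    ]
    return [(n, b, np.asarray(p, float)) for n, b, p in markers]


def synthesize_markers(model: ChainModel, series: QSeries, noise_sd: float = 0.0,
                       seed: Optional[int] = None,
                       markers: Optional[Sequence] = None) -> MarkerSet:
    """Marker world trajectories from forward kinematics plus i.i.d.
    Gaussian capture noise per axis (deterministic given ``seed``)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    markers = list(markers) if markers is not None else default_marker_set(model)
    rng = np.random.default_rng(seed)
    traj = {name: np.empty((len(series), 3)) for name, _, _ in markers}
    for i in range(len(series)):
        frames = model.forward_kinematics(series.values[i])
        for name, body, p in markers:
            traj[name][i] = frames[body].transform_point(p)
    if noise_sd > 0:
        for name, _, _ in markers:
            traj[name] += rng.normal(0.0, noise_sd, traj[name].shape)
    dts = np.diff(series.times)
    rate = 1.0 / dts[0] if len(dts) else 100.0
    return MarkerSet(markers, traj, series.times.copy(), rate)


# ---------------------------------------------------------------------------
# inverse kinematics


@dataclass
class IKResult:
    series: QSeries
    rms_errors: np.ndarray          # per-frame RMS marker residual, m
    converged: np.ndarray           # per-frame flag


def _marker_residual_jac(model: ChainModel, q: np.ndarray, markers, obs_frame):
    frames = model.forward_kinematics(q)
    res = []
    jac = []
    for name, body, p in markers:
        pred = frames[body].transform_point(p)
        res.append(pred - obs_frame[name])
        jac.append(model.point_jacobian(q, body, p, frames))
    return np.concatenate(res), np.vstack(jac)


def inverse_kinematics(model: ChainModel, marker_set: MarkerSet,
                       q0: Optional[np.ndarray] = None, max_iter: int = 100,
                       tol: float = 1e-12) -> IKResult:
    """Per-frame Gauss–Newton marker fit, warm-started frame to frame.

    Requires at least 3 non-collinear markers on the moving subtree;
    frames that fail to converge within ``max_iter`` are flagged.
    """
    moving = [m for m in marker_set.markers if m[1] != model.root]
    if len(moving) < 3:
        raise ValueError("need at least 3 markers on moving bodies for IK")
    pts = np.array([p for _, _, p in moving])
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("markers are collinear; the pose is unobservable")

    n = len(marker_set.times)
    values = np.zeros((n, model.n_dof))
    rms = np.zeros(n)
    ok = np.ones(n, bool)
    q = np.zeros(model.n_dof) if q0 is None else np.asarray(q0, float).copy()
    for i in range(n):
        obs = {name: marker_set.trajectories[name][i] for name, _, _ in marker_set.markers}
        converged = False
        for _ in range(max_iter):
            r, J = _marker_residual_jac(model, q, marker_set.markers, obs)
            step, *_ = np.linalg.lstsq(J, -r, rcond=None)
            q = q + step
            if np.linalg.norm(step) < tol:
                converged = True
                break
        r, _ = _marker_residual_jac(model, q, marker_set.markers, obs)
        rms[i] = float(np.sqrt(np.mean(np.sum(r.reshape(-1, 3) ** 2, axis=1))))
        ok[i] = converged
        values[i] = q
    return IKResult(QSeries(marker_set.times.copy(), values, list(model.coord_names)),
                    rms, ok)


# ---------------------------------------------------------------------------
# time stretch & quasi-static screening


def time_stretch(series: QSeries, factor: float = DEFAULT_TIME_STRETCH) -> QSeries:
    """Stretch the time base by ``factor``; sample values untouched.
    Implied velocities scale by 1/factor, accelerations by 1/factor²."""
    if factor <= 0:
        raise ValueError("stretch factor must be > 0")
    return QSeries(series.times * factor, series.values.copy(), list(series.coord_names))


def peak_angular_acceleration(series: QSeries) -> float:
    """Max |second central difference| of any coordinate (rad/s²)."""
    if len(series) < 3:
        return 0.0
    t = series.times
    x = series.values
    acc = np.empty((len(t) - 2, x.shape[1]))
    for i in range(1, len(t) - 1):
        dt1, dt2 = t[i] - t[i - 1], t[i + 1] - t[i]
        acc[i - 1] = 2 * (dt1 * x[i + 1] - (dt1 + dt2) * x[i] + dt2 * x[i - 1]) \
            / (dt1 * dt2 * (dt1 + dt2))
    return float(np.abs(acc).max())


def passes_quasi_static(series: QSeries,
                        limit: float = QUASI_STATIC_ACC_LIMIT) -> bool:
    """Quasi-static acceptance filter: peak implied angular acceleration
    below ``limit`` (the stretched series passes, raw noisy ones fail)."""
    return peak_angular_acceleration(series) < limit
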