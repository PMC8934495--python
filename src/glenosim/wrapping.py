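"""Muscle path geometry: straight polylines, via points, and
single-obstacle wrapping over spheres and ellipsoids.

A path is anchored at its origin and insertion, may pass through via
points (frictionless eyelets fixed to a body), and may be deflected by
at most one wrap surface per segment.  Sphere wrapping is solved in
closed form in the plane through the two end points and the centre;
ellipsoid wrapping discretizes the on-surface portion as a polyline of
surface points and minimizes total length, seeded from the scaled-sphere
solution.  Moment arms follow the tendon-excursion definition
r = −dL/dq, available both by central finite differences and through
the analytic anchor-Jacobian form used by the equilibrium assembly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .chain import ChainModel, Configuration
from .geometry import Frame

_N_SURFACE_PTS = 8  # interior polyline points for ellipsoid wrapping


@dataclass
class WrapSurface:
    """Sphere or ellipsoid obstacle fixed to a body.

    ``radii`` are the three semi-axes (m) in the surface's local frame
    (``orientation_local`` relative to the owning body); a sphere has
    equal radii.  ``active_muscles`` lists the muscle names this surface
    may deflect.
    """

    name: str
    kind: str
    body: str
    center_local: np.ndarray
    radii: np.ndarray
    orientation_local: np.ndarray = field(default_factory=lambda: np.eye(3))
    active_muscles: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.center_local = np.asarray(self.center_local, float)
        self.radii = np.asarray(self.radii, float)
        self.orientation_local = np.asarray(self.orientation_local, float)
        if self.kind not in ("sphere", "ellipsoid"):
            raise ValueError(f"wrap {self.name}: kind must be sphere or ellipsoid")
        if np.any(self.radii <= 0):
            raise ValueError(f"wrap {self.name}: radii must be positive")
        if self.kind == "sphere" and not np.allclose(self.radii, self.radii[0]):
            raise ValueError(f"wrap {self.name}: sphere requires equal radii")

    @property
    def radius(self) -> float:
        return float(self.radii[0])


@dataclass
class MusclePathSpec:
    """Origin → (via points) → insertion, with optional wrap assignment."""

    origin: Tuple[str, np.ndarray]
    insertion: Tuple[str, np.ndarray]
    via_points: List[Tuple[str, np.ndarray]] = field(default_factory=list)
    wrap_assignments: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.origin = (self.origin[0], np.asarray(self.origin[1], float))
        self.insertion = (self.insertion[0], np.asarray(self.insertion[1], float))
        self.via_points = [(b, np.asarray(p, float)) for b, p in self.via_points]
        if (self.origin[0] == self.insertion[0]
                and np.allclose(self.origin[1], self.insertion[1])):
            raise ValueError("muscle origin and insertion coincide")

    def fixed_points(self) -> List[Tuple[str, np.ndarray]]:
        return [self.origin, *self.via_points, self.insertion]


@dataclass
class PathSolution:
    """Solved geometric path at one configuration.

    ``anchors`` are the mechanically meaningful points — fixed points
    plus wrap tangent points, each owned by a body — used for
    virtual-work torques and joint reaction forces.  ``waypoints_world``
    additionally samples wrap arcs for display.  ``length`` uses the
    exact arc length on spheres.
    """

    waypoints_world: np.ndarray
    length: float
    wrapped: Dict[str, bool]
    anchors: List[Tuple[str, np.ndarray]]
    # consecutive anchor pairs whose straight-line distance varies with q
    # (arc/on-surface chords between same-body anchors drop out naturally)


def _segment_sphere_geometry(p1, p2, c, r):
    """Closed-form tangent–arc–tangent wrap in the p1/p2/centre plane.

    Returns (length, t1, t2, arc_angle) or None when the straight
    segment clears (or merely grazes) the sphere.
    """
    v1, v2 = p1 - c, p2 - c
    d1, d2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if d1 < r - 1e-12 or d2 < r - 1e-12:
        raise ValueError("path end point lies inside the wrap sphere")
    d1 = max(d1, r)
    d2 = max(d2, r)
    cosa = np.clip(v1 @ v2 / (d1 * d2), -1.0, 1.0)
    alpha = np.arccos(cosa)
    beta1 = np.arccos(np.clip(r / d1, -1.0, 1.0))
    beta2 = np.arccos(np.clip(r / d2, -1.0, 1.0))
    arc = alpha - beta1 - beta2
    if arc <= 0:
        return None  # line of sight (grazing ties break to unwrapped)
    # plane basis
    n = np.cross(v1, v2)
    nn = np.linalg.norm(n)
    if nn < 1e-14:  # collinear through centre: wrap plane undefined; pick any
        n = np.cross(v1, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-12:
            n = np.cross(v1, np.array([0.0, 1.0, 0.0]))
        nn = np.linalg.norm(n)
    n = n / nn
    e1 = v1 / d1
    e2 = np.cross(n, e1)  # in-plane, oriented from v1 toward v2
    t1 = c + r * (np.cos(beta1) * e1 + np.sin(beta1) * e2)
    phi2 = alpha - beta2  # angle of t2 from e1
    t2 = c + r * (np.cos(phi2) * e1 + np.sin(phi2) * e2)
    length = np.sqrt(max(d1 ** 2 - r ** 2, 0.0)) + r * arc + np.sqrt(max(d2 ** 2 - r ** 2, 0.0))
    return length, t1, t2, arc


def _sphere_arc_points(c, r, t1, t2, n_pts=9):
    u1 = (t1 - c) / r
    u2 = (t2 - c) / r
    ang = np.arccos(np.clip(u1 @ u2, -1.0, 1.0))
    axis = np.cross(u1, u2)
    na = np.linalg.norm(axis)
    if na < 1e-14 or ang < 1e-12:
        return np.array([t1, t2])
    axis /= na
    ts = np.linspace(0.0, ang, n_pts)
    from scipy.spatial.transform import Rotation
    return np.array([c + r * (Rotation.from_rotvec(axis * t).as_matrix() @ u1) for t in ts])


# -- ellipsoid ---------------------------------------------------------------

def _ellipsoid_world(surface: WrapSurface, frames: Dict[str, Frame]):
    f = frames[surface.body]
    centre = f.transform_point(surface.center_local)
    R = f.rotation @ surface.orientation_local  # world←surface axes
    return centre, R


def _to_surface_coords(p, centre, R, radii):
    return (R.T @ (p - centre)) / radii


def _segment_hits_unit_sphere(a, b) -> bool:
    """Does the segment a→b (both outside) intersect the unit sphere?"""
    d = b - a
    dd = d @ d
    if dd < 1e-30:
        return False
    t = np.clip(-(a @ d) / dd, 0.0, 1.0)
    closest = a + t * d
    return bool(closest @ closest < 1.0 and 0.0 < t < 1.0)


def _sph_to_vec(u, v):
    sv = np.sin(v)
    return np.array([sv * np.cos(u), sv * np.sin(u), np.cos(v)])


def _vec_to_sph(x):
    x = x / np.linalg.norm(x)
    v = np.arccos(np.clip(x[2], -1.0, 1.0))
    u = np.arctan2(x[1], x[0])
    return u, v


def _solve_ellipsoid_wrap(p1, p2, centre, R, radii, n_pts=_N_SURFACE_PTS):
    """Shortest polyline p1 → s_1..s_n (on surface) → p2.

    Surface points are parameterized by spherical angles of the scaled
    ellipsoid; the initial guess is the exact sphere solution in the
    scaled space.  Returns (length, surface_points_world) or None if
    the straight segment clears the surface.
    """
    a1 = _to_surface_coords(p1, centre, R, radii)
    a2 = _to_surface_coords(p2, centre, R, radii)
    r1, r2 = np.linalg.norm(a1), np.linalg.norm(a2)
    if r1 < 1.0 - 1e-9 or r2 < 1.0 - 1e-9:
        raise ValueError("path end point lies inside the wrap ellipsoid")
    if not _segment_hits_unit_sphere(a1, a2):
        return None
    # seed: sphere wrap in scaled space
    geo = _segment_sphere_geometry(a1, a2, np.zeros(3), 1.0)
    if geo is None:
        return None
    _, t1, t2, _ = geo
    arc = _sphere_arc_points(np.zeros(3), 1.0, t1, t2, n_pts)
    x0 = np.concatenate([np.array(_vec_to_sph(s)) for s in arc])

    radii = np.asarray(radii, float)

    def surface_points(x):
        uv = x.reshape(-1, 2)
        return np.array([_sph_to_vec(u, v) * radii for u, v in uv])  # surface frame, metric

    pe1 = R.T @ (p1 - centre)
    pe2 = R.T @ (p2 - centre)

    def fun_grad(x):
        s = surface_points(x)
        pts = np.vstack([pe1, s, pe2])
        diffs = np.diff(pts, axis=0)
        lens = np.linalg.norm(diffs, axis=1)
        lens = np.maximum(lens, 1e-12)
        units = diffs / lens[:, None]
        # dL/ds_i = unit(prev seg) - unit(next seg)
        dL_ds = units[:-1] - units[1:]
        uv = x.reshape(-1, 2)
        grad = np.empty_like(uv)
        for i, (u, v) in enumerate(uv):
            sv, cv = np.sin(v), np.cos(v)
            du = radii * np.array([-sv * np.sin(u), sv * np.cos(u), 0.0])
            dv = radii * np.array([cv * np.cos(u), cv * np.sin(u), -sv])
            grad[i, 0] = dL_ds[i] @ du
            grad[i, 1] = dL_ds[i] @ dv
        return float(lens.sum()), grad.ravel()

    res = minimize(fun_grad, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-10})
    s = surface_points(res.x)
    pts_world = s @ R.T + centre
    pts = np.vstack([pe1, s, pe2])
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return length, pts_world


# -- public API --------------------------------------------------------------

def solve_path(spec: MusclePathSpec, frames: Dict[str, Frame],
               wraps: Optional[Dict[str, WrapSurface]] = None,
               muscle_name: str = "") -> PathSolution:
    """Solve the geometric path of one muscle at the given body poses.

    Wrapping is evaluated per straight segment against the (single)
    assigned surface; a segment that merely grazes reports
    ``wrapped=False``.
    """
    wraps = wraps or {}
    fixed = spec.fixed_points()
    for body, _ in fixed:
        if body not in frames:
            raise KeyError(f"no frame for body {body}")
    pts = [(b, frames[b].transform_point(p)) for b, p in fixed]

    surfaces = [wraps[wn] for wn in spec.wrap_assignments if wn in wraps]
    wrapped_flags = {wn: False for wn in spec.wrap_assignments}

    anchors: List[Tuple[str, np.ndarray]] = []
    display: List[np.ndarray] = []
    total = 0.0
    for (body_a, pa), (body_b, pb) in zip(pts[:-1], pts[1:]):
        anchors.append((body_a, pa))
        display.append(pa)
        seg_handled = False
        for surf in surfaces:
            if surf.kind == "sphere":
                centre, _ = _ellipsoid_world(surf, frames)
                try:
                    geo = _segment_sphere_geometry(pa, pb, centre, surf.radius)
                except ValueError as e:
                    raise ValueError(
                        f"muscle {muscle_name or '<path>'} / wrap {surf.name}: {e}") from e
                if geo is not None:
                    length, t1, t2, _ = geo
                    total += length
                    anchors.append((surf.body, t1))
                    anchors.append((surf.body, t2))
                    display.extend(_sphere_arc_points(centre, surf.radius, t1, t2))
                    wrapped_flags[surf.name] = True
                    seg_handled = True
            else:
                centre, R = _ellipsoid_world(surf, frames)
                try:
                    sol = _solve_ellipsoid_wrap(pa, pb, centre, R, surf.radii)
                except ValueError as e:
                    raise ValueError(
                        f"muscle {muscle_name or '<path>'} / wrap {surf.name}: {e}") from e
                if sol is not None:
                    length, s_world = sol
                    total += length
                    for sp in s_world:
                        anchors.append((surf.body, sp))
                    display.extend(s_world)
                    wrapped_flags[surf.name] = True
                    seg_handled = True
            if seg_handled:
                break
        if not seg_handled:
            total += float(np.linalg.norm(pb - pa))
    anchors.append(pts[-1])
    display.append(pts[-1][1])
    return PathSolution(np.array(display), float(total), wrapped_flags, anchors)


def path_length(model: ChainModel, q, muscle) -> float:
    frames = model.forward_kinematics(q)
    return solve_path(muscle.path, frames, model.wraps, muscle.name).length


def moment_arm(model: ChainModel, q, muscle, dof_index: int,
               h: float = 1e-5) -> float:
    """Tendon-excursion moment arm r = −dL/dq_dof (m) by central
    finite difference of the solved path length."""
    if not (1e-6 <= h <= 1e-2):
        raise ValueError("step h must lie in [1e-6, 1e-2] rad")
    qv = np.array(q.q if isinstance(q, Configuration) else q, float)
    qp, qm = qv.copy(), qv.copy()
    qp[dof_index] += h
    qm[dof_index] -= h
    try:
        lp = path_length(model, qp, muscle)
        lm = path_length(model, qm, muscle)
    except ValueError as e:
        raise ValueError(f"path infeasible at perturbed configuration: {e}") from e
    return -(lp - lm) / (2.0 * h)


def excursion_gradient(model: ChainModel, q, frames, sol: PathSolution) -> np.ndarray:
    """Analytic dL/dq from anchor Jacobians: Σ_seg û·(J_b − J_a).

    By the envelope theorem wrap tangent points count as material points
    of the wrap body; arc lengths between same-body anchors are rigid
    and drop out.  ``-excursion_gradient`` is the generalized torque per
    unit muscle tension.
    """
    grad = np.zeros(model.n_dof)
    for (body_a, pa), (body_b, pb) in zip(sol.anchors[:-1], sol.anchors[1:]):
        d = pb - pa
        n = np.linalg.norm(d)
        if n < 1e-12:
            continue
        if body_a == body_b:
            continue  # rigid chord: constant length
        u = d / n
        Ja = model.point_jacobian(q, body_a, frames[body_a].inverse().transform_point(pa), frames)
        Jb = model.point_jacobian(q, body_b, frames[body_b].inverse().transform_point(pb), frames)
        grad += u @ (Jb - Ja)
    return grad


def anchor_forces_per_unit_tension(sol: PathSolution) -> Dict[str, np.ndarray]:
    """Net muscle force (per unit tension) applied to each body.

    Each straight segment pulls its two end anchors toward each other;
    summing per owning body gives the free-body contributions used by
    the joint-reaction computation.
    """
    forces: Dict[str, np.ndarray] = {}
    for (body_a, pa), (body_b, pb) in zip(sol.anchors[:-1], sol.anchors[1:]):
        d = pb - pa
        n = np.linalg.norm(d)
        if n < 1e-12:
            continue
        u = d / n
        forces[body_a] = forces.get(body_a, np.zeros(3)) + u
        forces[body_b] = forces.get(body_b, np.zeros(3)) - u
    return forces


def build_wrap_for_implant(implant: str, deltoid_half_thickness: float = 0.010,
                           body: str = "scapula", center_local=(0.0, 0.0, 0.0),
                           orientation_local=None, name: Optional[str] = None,
                           active_muscles=None) -> WrapSurface:
    """Wrap surface for a prosthesis, inflated by half the deltoid
    thickness so the muscle mid-line deflects realistically.

    RSP: 36 mm glenosphere → sphere of diameter 36 mm + 2×inflation.
    DBSP: 55 mm glenoid ring → ellipsoid with in-plane diameters
    55 mm + 2×inflation and out-of-plane diameter 28 mm.
    """
    implant = implant.upper()
    if implant == "RSP":
        r = 0.036 / 2 + deltoid_half_thickness
        return WrapSurface(name or "rsp_glenosphere_wrap", "sphere", body,
                           center_local, np.array([r, r, r]),
                           active_muscles=active_muscles or [])
    if implant == "DBSP":
        r_plane = 0.055 / 2 + deltoid_half_thickness
        radii = np.array([r_plane, r_plane, 0.028 / 2])
        return WrapSurface(name or "dbsp_ring_wrap", "ellipsoid", body,
                           center_local, radii,
                           orientation_local=(np.eye(3) if orientation_local is None
                                              else np.asarray(orientation_local, float)),
                           active_muscles=active_muscles or [])
    raise ValueError(f"unknown implant {implant!r}; expected RSP or DBSP")
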