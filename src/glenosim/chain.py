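"""Rigid-body kinematic chain: bodies, joints, forward kinematics,
point Jacobians and quasi-static gravity torques.

The joint taxonomy is fixed / hinge (1 rotational DOF) / gimbal (2) /
ball (3).  Multi-axis joints are ordered intrinsic rotations about the
declared axes, all sharing the joint centre (axes intersect).  The joint
graph must be a tree rooted at the first body (the thorax).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import Frame, rotation_about

JOINT_DOF = {"fixed": 0, "hinge": 1, "gimbal": 2, "ball": 3}


@dataclass
class BodySegment:
    """One rigid segment with its mass properties.

    ``attached_point_loads`` carries rigidly attached extra masses, e.g.
    the 2 kg hand-held weight, as (point_local, mass_kg) pairs.
    """

    name: str
    mass: float = 0.0
    com_local: np.ndarray = field(default_factory=lambda: np.zeros(3))
    attached_point_loads: List[Tuple[np.ndarray, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.com_local = np.asarray(self.com_local, float)
        if self.mass < 0:
            raise ValueError(f"body {self.name}: mass must be >= 0")
        self.attached_point_loads = [
            (np.asarray(p, float), float(m)) for p, m in self.attached_point_loads
        ]
        for _, m in self.attached_point_loads:
            if m < 0:
                raise ValueError(f"body {self.name}: attached mass must be >= 0")


@dataclass
class JointSpec:
    """Joint between ``parent_body`` and ``child_body``.

    ``axes`` holds one unit 3-vector per rotational DOF (in the joint
    frame reached through ``parent_frame_offset``).  ``driven`` marks a
    coordinate that is kinematically prescribed (e.g. the scapular
    rhythm); its reserve actuator is a legitimate drive rather than a
    model deficiency.
    """

    name: str
    kind: str
    parent_body: str
    child_body: str
    parent_frame_offset: Frame = field(default_factory=Frame.identity)
    child_frame_offset: Frame = field(default_factory=Frame.identity)
    axes: Sequence[np.ndarray] = field(default_factory=list)
    coord_names: Optional[List[str]] = None
    driven: bool = False

    def __post_init__(self) -> None:
        if self.kind not in JOINT_DOF:
            raise ValueError(
                f"joint {self.name}: unknown kind {self.kind!r}; "
                f"expected one of {sorted(JOINT_DOF)}")
        self.axes = [np.asarray(a, float) for a in self.axes]
        if len(self.axes) != JOINT_DOF[self.kind]:
            raise ValueError(
                f"joint {self.name}: kind {self.kind!r} requires "
                f"{JOINT_DOF[self.kind]} axes, got {len(self.axes)}")
        for a in self.axes:
            n = np.linalg.norm(a)
            if abs(n - 1.0) > 1e-8:
                raise ValueError(f"joint {self.name}: axes must be unit vectors")
        if self.coord_names is None:
            self.coord_names = [f"{self.name}_q{i}" for i in range(self.dof)]
        if len(self.coord_names) != self.dof:
            raise ValueError(f"joint {self.name}: coord_names length mismatch")

    @property
    def dof(self) -> int:
        return JOINT_DOF[self.kind]


@dataclass
class Configuration:
    """Generalized-coordinate vector over all joint DOFs (radians),
    ordered by the model's joint-tree traversal."""

    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.atleast_1d(np.asarray(self.q, float))

    def __len__(self) -> int:
        return len(self.q)


class ChainModel:
    """The full rigid-body / joint / muscle / wrap assembly for one
    shoulder configuration."""

    def __init__(self, bodies: Iterable[BodySegment], joints: Iterable[JointSpec],
                 muscles=None, wraps=None, gravity=(0.0, -9.81, 0.0),
                 gh_joint_name: Optional[str] = None, name: str = "model",
                 gh_coord_names: Optional[List[str]] = None):
        self.name = name
        self.bodies: Dict[str, BodySegment] = {}
        for b in bodies:
            if b.name in self.bodies:
                raise ValueError(f"duplicate body {b.name}")
            self.bodies[b.name] = b
        self.joints: List[JointSpec] = list(joints)
        self.muscles = list(muscles) if muscles else []
        self.wraps: Dict[str, "object"] = dict(wraps) if wraps else {}
        self.gravity = np.asarray(gravity, float)
        self.gh_joint_name = gh_joint_name
        self.gh_coord_names = gh_coord_names or []
        self._validate_tree()
        self._index()

    # -- structure ---------------------------------------------------------
    def _validate_tree(self) -> None:
        names = set(self.bodies)
        seen_children = set()
        for j in self.joints:
            for b in (j.parent_body, j.child_body):
                if b not in names:
                    raise ValueError(f"joint {j.name}: unknown body {b}")
            if j.child_body in seen_children:
                raise ValueError(f"body {j.child_body} has two parent joints")
            seen_children.add(j.child_body)
        roots = names - seen_children
        if len(roots) != 1:
            raise ValueError(f"joint graph must be a tree with one root, got roots {sorted(roots)}")
        self.root = next(iter(roots))
        # topological order from root
        by_parent: Dict[str, List[JointSpec]] = {}
        for j in self.joints:
            by_parent.setdefault(j.parent_body, []).append(j)
        order: List[JointSpec] = []
        stack = [self.root]
        while stack:
            b = stack.pop(0)
            for j in by_parent.get(b, []):
                order.append(j)
                stack.append(j.child_body)
        if len(order) != len(self.joints):
            raise ValueError("joint graph contains a cycle or disconnected part")
        self.joints = order

    def _index(self) -> None:
        self.coord_names: List[str] = []
        self._joint_q_slices: Dict[str, slice] = {}
        i = 0
        for j in self.joints:
            self._joint_q_slices[j.name] = slice(i, i + j.dof)
            self.coord_names.extend(j.coord_names)
            i += j.dof
        self.n_dof = i
        self._parent_joint = {j.child_body: j for j in self.joints}
        self.driven_mask = np.zeros(self.n_dof, bool)
        for j in self.joints:
            if j.driven:
                self.driven_mask[self._joint_q_slices[j.name]] = True

    def coord_index(self, name: str) -> int:
        return self.coord_names.index(name)

    def joint(self, name: str) -> JointSpec:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(f"unknown joint {name}")

    def q_slice(self, joint_name: str) -> slice:
        return self._joint_q_slices[joint_name]

    def zero_q(self) -> Configuration:
        return Configuration(np.zeros(self.n_dof))

    def named_q(self, **angles_rad) -> Configuration:
        q = np.zeros(self.n_dof)
        for name, val in angles_rad.items():
            q[self.coord_index(name)] = val
        return Configuration(q)

    def path_to_root(self, body: str) -> List[JointSpec]:
        """Joints from the root down to ``body`` in order."""
        chain: List[JointSpec] = []
        while body != self.root:
            j = self._parent_joint[body]
            chain.append(j)
            body = j.parent_body
        return chain[::-1]

    def distal_bodies(self, joint_name: str) -> List[str]:
        """Bodies in the subtree hanging from ``joint_name`` (child side)."""
        j = self.joint(joint_name)
        out = [j.child_body]
        frontier = [j.child_body]
        while frontier:
            b = frontier.pop()
            for jj in self.joints:
                if jj.parent_body == b:
                    out.append(jj.child_body)
                    frontier.append(jj.child_body)
        return out

    # -- kinematics --------------------------------------------------------
    def _check_q(self, q: Configuration) -> np.ndarray:
        qv = q.q if isinstance(q, Configuration) else np.atleast_1d(np.asarray(q, float))
        if len(qv) != self.n_dof:
            for j in self.joints:
                sl = self._joint_q_slices[j.name]
                if sl.stop > len(qv):
                    raise ValueError(
                        f"configuration has {len(qv)} coordinates but model needs "
                        f"{self.n_dof}; joint {j.name} expects {j.dof} DOF at {sl}")
            raise ValueError(f"configuration length {len(qv)} != model DOF {self.n_dof}")
        return qv

    def forward_kinematics(self, q) -> Dict[str, Frame]:
        qv = self._check_q(q)
        frames = {self.root: Frame.identity()}
        for j in self.joints:
            parent = frames[j.parent_body]
            jf = parent @ j.parent_frame_offset
            qj = qv[self._joint_q_slices[j.name]]
            rot = np.eye(3)
            for axis, angle in zip(j.axes, qj):
                rot = rot @ rotation_about(axis, angle)
            frames[j.child_body] = jf @ Frame(rot) @ j.child_frame_offset
            if j.kind == "ball":
                _warn_if_singular(j, qj)
        return frames

    def joint_world_axes(self, q, frames: Optional[Dict[str, Frame]] = None):
        """Per rotational coordinate: (world axis, world joint centre).

        Axis i of a multi-axis joint is expressed after the preceding
        intrinsic rotations, which is what the Jacobian needs.
        """
        qv = self._check_q(q)
        if frames is None:
            frames = self.forward_kinematics(qv)
        info = []
        for j in self.joints:
            if j.dof == 0:
                continue
            jf = frames[j.parent_body] @ j.parent_frame_offset
            centre = jf.translation
            r = jf.rotation
            qj = qv[self._joint_q_slices[j.name]]
            rot = np.eye(3)
            for axis, angle in zip(j.axes, qj):
                info.append((r @ rot @ axis, centre, j))
                rot = rot @ rotation_about(axis, angle)
        return info

    def point_jacobian(self, q, body: str, point_local, frames=None) -> np.ndarray:
        """3×DOF matrix: column j = ∂(world position of point)/∂q_j (m/rad)."""
        if body not in self.bodies:
            raise KeyError(f"unknown body {body}")
        qv = self._check_q(q)
        if frames is None:
            frames = self.forward_kinematics(qv)
        p_world = frames[body].transform_point(point_local)
        J = np.zeros((3, self.n_dof))
        chain = {j.name for j in self.path_to_root(body)}
        col = 0
        for j in self.joints:
            if j.dof == 0:
                continue
            sl = self._joint_q_slices[j.name]
            if j.name in chain:
                jf = frames[j.parent_body] @ j.parent_frame_offset
                centre = jf.translation
                r = jf.rotation
                qj = qv[sl]
                rot = np.eye(3)
                for k, (axis, angle) in enumerate(zip(j.axes, qj)):
                    w = r @ rot @ axis
                    J[:, sl.start + k] = np.cross(w, p_world - centre)
                    rot = rot @ rotation_about(axis, angle)
            col += j.dof
        return J

    def gravity_load_torques(self, q) -> np.ndarray:
        """Generalized gravity torque τ_ext (N·m): Σ Jᵀ(m·g) over body
        COMs and attached point loads.  Purely static."""
        qv = self._check_q(q)
        frames = self.forward_kinematics(qv)
        tau = np.zeros(self.n_dof)
        for b in self.bodies.values():
            if b.mass > 0:
                J = self.point_jacobian(qv, b.name, b.com_local, frames)
                tau += J.T @ (b.mass * self.gravity)
            for point, m in b.attached_point_loads:
                if m > 0:
                    J = self.point_jacobian(qv, b.name, point, frames)
                    tau += J.T @ (m * self.gravity)
        return tau

    def potential_energy(self, q) -> float:
        """Gravitational potential energy −Σ m g·p (J); its negative
        q-gradient equals ``gravity_load_torques``."""
        frames = self.forward_kinematics(q)
        v = 0.0
        for b in self.bodies.values():
            if b.mass > 0:
                v -= b.mass * self.gravity @ frames[b.name].transform_point(b.com_local)
            for point, m in b.attached_point_loads:
                if m > 0:
                    v -= m * self.gravity @ frames[b.name].transform_point(point)
        return v

    def total_distal_weight(self, joint_name: str) -> float:
        """Total suspended mass (kg) distal to a joint, loads included."""
        mass = 0.0
        for name in self.distal_bodies(joint_name):
            b = self.bodies[name]
            mass += b.mass + sum(m for _, m in b.attached_point_loads)
        return mass


def _warn_if_singular(joint: JointSpec, qj: np.ndarray, tol_deg: float = 2.0) -> None:
    """Warn when the first and (rotated) last axes of a 3-axis joint
    align — the Euler parameterization loses a DOF there."""
    mid = rotation_about(joint.axes[1], qj[1])
    a3 = mid @ joint.axes[2]
    if abs(abs(float(joint.axes[0] @ a3)) - 1.0) < 1.0 - np.cos(np.deg2rad(tol_deg)):
        warnings.warn(
            f"joint {joint.name}: rotation axes nearly aligned "
            f"(gimbal-lock) at q={np.rad2deg(qj).round(2)} deg", RuntimeWarning,
            stacklevel=3)
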