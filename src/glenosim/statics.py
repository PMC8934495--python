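"""Quasi-static inverse statics, static-optimization redundancy
resolution and gleno-humeral joint reaction force.

Per pose: the generalized torques required to balance gravity (and the
hand-held load) are computed from the chain, the muscle moment-arm
matrix and per-muscle activation→force gains are assembled from the
solved paths, and activations are found by minimizing

    Σ a_i²  +  w_r · Σ (reserve_j / reserve_gain_j)²

subject to R·diag(f_gain)·a + reserve = τ_required and 0 ≤ a ≤ 1.
Eliminating the reserves turns this into a box-constrained linear least
squares problem, solved deterministically.  Reserve actuators at every
DOF guarantee feasibility; coordinates marked ``driven`` (kinematically
prescribed, e.g. the scapular rhythm) carry ideal drives whose torque
is excluded from the penalty and from the feasibility verdict.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.optimize import lsq_linear

from .chain import ChainModel
from .muscles import force_gain
from .wrapping import (anchor_forces_per_unit_tension, excursion_gradient,
                       solve_path)

RESERVE_WEIGHT = 1.0e4     # penalty weight w_r on reserve torques
RESERVE_GAIN = 1.0         # reserve normalization, N·m
RESERVE_ENGAGED_TOL = 1e-2  # N·m: above this a reserve counts as engaged


@dataclass
class EquilibriumSystem:
    """One pose's linearized muscle equilibrium."""

    R: np.ndarray              # DOF × muscles moment-arm matrix, m
    f_gain: np.ndarray         # per-muscle a→F gain, N
    tau_required: np.ndarray   # N·m
    bounds: tuple = (0.0, 1.0)
    reserve_gains: Optional[np.ndarray] = None   # N·m per DOF
    reserve_weight: float = RESERVE_WEIGHT
    free_reserve_mask: Optional[np.ndarray] = None  # True = unpenalized drive

    def __post_init__(self) -> None:
        self.R = np.atleast_2d(np.asarray(self.R, float))
        self.f_gain = np.atleast_1d(np.asarray(self.f_gain, float))
        self.tau_required = np.atleast_1d(np.asarray(self.tau_required, float))
        n_dof, n_mus = self.R.shape
        if len(self.f_gain) != n_mus or len(self.tau_required) != n_dof:
            raise ValueError("inconsistent equilibrium system dimensions")
        if not np.all(np.isfinite(self.tau_required)):
            raise ValueError("tau_required must be finite")
        if self.reserve_gains is None:
            self.reserve_gains = np.full(n_dof, RESERVE_GAIN)
        if self.free_reserve_mask is None:
            self.free_reserve_mask = np.zeros(n_dof, bool)


@dataclass
class SolveReport:
    activations: np.ndarray
    forces: np.ndarray
    reserve_torques: np.ndarray
    objective_value: float
    residual_norm: float
    status: str
    solver_message: str = ""


@dataclass
class JointReactionForce:
    """Net force transmitted across a joint (world axes, N)."""

    force_world: np.ndarray
    joint: str
    magnitude: float = field(init=False)

    def __post_init__(self) -> None:
        self.force_world = np.asarray(self.force_world, float)
        self.magnitude = float(np.linalg.norm(self.force_world))


def required_torques(model: ChainModel, q) -> np.ndarray:
    """Generalized torques the actuators must supply: the negative of
    the gravity loads (quasi-static, no inertial terms)."""
    return -model.gravity_load_torques(q)


def static_optimization(system: EquilibriumSystem) -> SolveReport:
    """Resolve muscle redundancy by the minimum Σ activation² criterion.

    The reserve-penalized QP is strictly convex, hence the minimizer is
    unique and the solve deterministic.
    """
    n_dof, n_mus = system.R.shape
    M = system.R * system.f_gain[None, :]       # torque per unit activation
    w = np.sqrt(system.reserve_weight) / system.reserve_gains
    w = np.where(system.free_reserve_mask, 0.0, w)
    lo, hi = system.bounds
    if n_mus == 0 or not np.any(np.abs(M) > 0):
        a = np.zeros(n_mus)
        res = None
    else:
        A = np.vstack([w[:, None] * M, np.eye(n_mus)])
        b = np.concatenate([w * system.tau_required, np.zeros(n_mus)])
        res = lsq_linear(A, b, bounds=(lo, hi), method="bvls", tol=1e-14)
        a = np.clip(res.x, lo, hi)
        if not res.success and res.status not in (0, 1, 2, 3):
            return SolveReport(a, a * system.f_gain, system.tau_required - M @ a,
                               np.inf, np.inf, "failed", res.message)
    reserves = system.tau_required - M @ a
    residual = system.tau_required - (M @ a + reserves)  # zero by construction
    penalized = reserves[~system.free_reserve_mask]
    gains = system.reserve_gains[~system.free_reserve_mask]
    objective = float(a @ a + system.reserve_weight * np.sum((penalized / gains) ** 2))
    engaged = np.any(np.abs(penalized) > RESERVE_ENGAGED_TOL)
    status = "infeasible_reserves_used" if engaged else "optimal"
    return SolveReport(a, a * system.f_gain, reserves, objective,
                       float(np.linalg.norm(residual)), status,
                       res.message if res is not None else "no active muscles")


def build_equilibrium_system(model: ChainModel, q,
                             frames=None) -> tuple:
    """Assemble (EquilibriumSystem, per-muscle PathSolution dict) at a pose.

    Moment arms come from the analytic tendon-excursion gradient
    (virtual work over path anchors); inactive muscles contribute zero
    columns.
    """
    if frames is None:
        frames = model.forward_kinematics(q)
    n = len(model.muscles)
    R = np.zeros((model.n_dof, n))
    gains = np.zeros(n)
    sols = {}
    for i, mus in enumerate(model.muscles):
        sol = solve_path(mus.path, frames, model.wraps, mus.name)
        sols[mus.name] = sol
        if not mus.active:
            continue
        R[:, i] = -excursion_gradient(model, q, frames, sol)
        gains[i] = force_gain(mus, sol.length)
    system = EquilibriumSystem(R=R, f_gain=gains,
                               tau_required=required_torques(model, q),
                               free_reserve_mask=model.driven_mask.copy())
    return system, sols


def joint_reaction_force(model: ChainModel, q, forces,
                         joint: str, frames=None,
                         path_solutions: Optional[Dict[str, object]] = None
                         ) -> JointReactionForce:
    """Free-body balance of the subtree distal to ``joint``.

    JRF = −(gravity + attached loads on distal bodies + net muscle
    forces applied to distal bodies), each muscle pulling its anchors
    along the local path tangents.  For the dual-bearing prosthesis the
    reported joint is the scapula–ring fixed joint, so the reaction is
    the load transmitted to the glenoid ring.
    """
    model.joint(joint)  # raises KeyError if unknown
    if frames is None:
        frames = model.forward_kinematics(q)
    distal = set(model.distal_bodies(joint))
    total = np.zeros(3)
    for name in distal:
        b = model.bodies[name]
        total += b.mass * model.gravity
        for point, m in b.attached_point_loads:
            total += m * model.gravity
    forces = np.atleast_1d(np.asarray(forces, float))
    for i, mus in enumerate(model.muscles):
        f = forces[i]
        if f <= 0:
            continue
        if path_solutions is not None and mus.name in path_solutions:
            sol = path_solutions[mus.name]
        else:
            sol = solve_path(mus.path, frames, model.wraps, mus.name)
        for body, unit in anchor_forces_per_unit_tension(sol).items():
            if body in distal:
                total += f * unit
    return JointReactionForce(-total, joint)
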