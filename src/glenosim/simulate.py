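"""Quasi-static motion solver: drives a shoulder model through a
joint-coordinate series, resolves muscle redundancy at every step and
records forces, activations, reserves and the gleno-humeral joint
reaction force."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .chain import ChainModel
from .motions import (ELBOW_FLEXION_DEG, MotionSpec, QSeries,
                      generate_trajectory, time_stretch)
from .statics import (build_equilibrium_system, joint_reaction_force,
                      static_optimization)

log = logging.getLogger(__name__)


@dataclass
class MotionResult:
    """Per-time-step outputs of one simulated motion."""

    model_name: str
    motion: str
    times: np.ndarray
    q_values: np.ndarray
    element_names: List[str]
    element_groups: Dict[str, str]
    element_fmax: Dict[str, float]
    element_active: Dict[str, bool]
    activations: np.ndarray          # n_steps × n_muscles
    forces: np.ndarray               # n_steps × n_muscles, N
    reserves: np.ndarray             # n_steps × DOF, N·m
    gh_torques: np.ndarray           # n_steps × 3, N·m (GH coordinates)
    jrf_world: np.ndarray            # n_steps × 3, N
    statuses: List[str] = field(default_factory=list)

    @property
    def jrf_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.jrf_world, axis=1)

    @property
    def force_series(self) -> Dict[str, np.ndarray]:
        return {n: self.forces[:, i] for i, n in enumerate(self.element_names)}

    @property
    def peak_gh_moment(self) -> float:
        """Peak norm of the required gleno-humeral torque vector."""
        return float(np.linalg.norm(self.gh_torques, axis=1).max())

    @property
    def n_failed(self) -> int:
        return sum(s == "failed" for s in self.statuses)


def solve_series(model: ChainModel, series: QSeries, motion: str = "") -> MotionResult:
    """Static optimization at every step of a coordinate series.

    Infeasible steps engage the reserve actuators, are flagged and kept
    (never silently dropped).
    """
    n = len(series)
    nm = len(model.muscles)
    gh_idx = [model.coord_index(c) for c in model.gh_coord_names]
    out = MotionResult(
        model_name=model.name, motion=motion,
        times=series.times.copy(), q_values=series.values.copy(),
        element_names=[m.name for m in model.muscles],
        element_groups={m.name: m.group for m in model.muscles},
        element_fmax={m.name: m.f_max for m in model.muscles},
        element_active={m.name: m.active for m in model.muscles},
        activations=np.zeros((n, nm)), forces=np.zeros((n, nm)),
        reserves=np.zeros((n, model.n_dof)), gh_torques=np.zeros((n, len(gh_idx))),
        jrf_world=np.zeros((n, 3)))
    for i in range(n):
        q = series.values[i]
        frames = model.forward_kinematics(q)
        system, sols = build_equilibrium_system(model, q, frames)
        report = static_optimization(system)
        out.activations[i] = report.activations
        out.forces[i] = report.forces
        out.reserves[i] = report.reserve_torques
        out.gh_torques[i] = system.tau_required[gh_idx]
        out.statuses.append(report.status)
        if report.status != "optimal":
            log.warning("%s/%s step %d: %s (max reserve %.3f N·m)",
                        model.name, motion, i, report.status,
                        np.abs(report.reserve_torques[~model.driven_mask]).max()
                        if np.any(~model.driven_mask) else 0.0)
        jrf = joint_reaction_force(model, q, report.forces, model.gh_joint_name,
                                   frames, sols)
        out.jrf_world[i] = jrf.force_world
    return out


def simulate_motion(builder, motion: str, n_steps: int = 25,
                    scapular_rhythm: bool = True,
                    stretch_factor: Optional[float] = None,
                    **builder_kwargs) -> MotionResult:
    """Build a model in the motion's posture, generate the protocol
    trajectory, optionally apply the quasi-static time stretch, and
    solve.  ``builder`` is one of the prosthesis-model builders."""
    model = builder(elbow_flexion_deg=ELBOW_FLEXION_DEG[motion], **builder_kwargs)
    spec = MotionSpec(motion, n_steps=n_steps, scapular_rhythm=scapular_rhythm)
    series = generate_trajectory(model, spec)
    if stretch_factor:
        series = time_stretch(series, stretch_factor)
    return solve_series(model, series, motion)
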