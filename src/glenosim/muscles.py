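"""Quasi-static Hill-type muscle force.

Each muscle element is a tensile force generator: F = a·f_max·f_L(l̃)
(+ optional passive term), with a rigid tendon (fiber length = path
length − tendon slack, clamped at zero) and no force–velocity factor —
the protocol is quasi-static so the velocity term is identically 1.
The active force–length curve is a Gaussian bell centred on the optimal
fiber length, truncated outside [0.5, 1.5]·l_opt.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .wrapping import MusclePathSpec

log = logging.getLogger(__name__)

DELTOID_GROUPS = ("anterior_deltoid", "middle_deltoid", "posterior_deltoid")
ROTATOR_CUFF_GROUPS = ("supraspinatus", "infraspinatus", "teres_minor", "subscapularis")

_FL_WIDTH = 0.45  # Gaussian width of the active force-length bell


@dataclass
class MuscleElement:
    """One tensile force-generating element of a muscle group."""

    name: str
    group: str
    f_max: float           # maximum isometric force, N
    l_opt: float           # optimal fiber length, m
    l_slack: float         # tendon slack length, m
    path: MusclePathSpec
    active: bool = True
    passive_enabled: bool = False

    def __post_init__(self) -> None:
        if self.f_max <= 0:
            raise ValueError(f"muscle {self.name}: f_max must be > 0")
        if self.l_opt <= 0:
            raise ValueError(f"muscle {self.name}: l_opt must be > 0")
        if self.l_slack < 0:
            raise ValueError(f"muscle {self.name}: l_slack must be >= 0")


@dataclass
class MuscleState:
    """Activation (dimensionless, in [0,1]) and tensile force (N)."""

    activation: float
    force: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.activation <= 1.0):
            raise ValueError("activation must lie in [0, 1]")
        if self.force < 0:
            raise ValueError("muscle force is tension-only (>= 0)")


def active_force_length(l_norm: float) -> float:
    """Active force–length scaling in [0, 1].

    Equals 1 at the optimal length, is symmetric about it, and is zero
    outside [0.5, 1.5] (truncated Gaussian bell).
    """
    l_norm = np.asarray(l_norm, float)
    if np.any(l_norm <= 0):
        raise ValueError("normalized fiber length must be positive")
    out = np.exp(-(((l_norm - 1.0) / _FL_WIDTH) ** 2))
    out = np.where((l_norm < 0.5) | (l_norm > 1.5), 0.0, out)
    return float(out) if out.ndim == 0 else out


def passive_force_length(l_norm) -> np.ndarray:
    """Exponential toe curve for the passive element (zero below l_opt)."""
    l_norm = np.asarray(l_norm, float)
    out = np.where(l_norm > 1.0, (np.exp(5.0 * (l_norm - 1.0)) - 1.0) / (np.exp(2.5) - 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def fiber_length(element: MuscleElement, path_length: float) -> float:
    """Rigid-tendon fiber length, clamped at >= 0."""
    return max(path_length - element.l_slack, 0.0)


def force_gain(element: MuscleElement, path_length: float) -> float:
    """dF/da at fixed geometry (N): f_max · f_L(l̃).  Zero when the
    element is deactivated or geometrically incapable."""
    if not element.active:
        return 0.0
    lf = fiber_length(element, path_length)
    if lf <= 0.0:
        log.warning("muscle %s: fiber length clamped to zero (path %.4f m <= slack %.4f m)",
                    element.name, path_length, element.l_slack)
        return 0.0
    return element.f_max * active_force_length(lf / element.l_opt)


def muscle_force(a: float, element: MuscleElement, path_length: float) -> float:
    """Tensile force (N) at activation ``a`` and the given path length.

    Linear in ``a`` at fixed geometry (this linearity is what turns the
    redundancy resolution into a convex QP); the passive term, disabled
    by default, adds an activation-independent offset.
    """
    if not (0.0 <= a <= 1.0):
        raise ValueError("activation must lie in [0, 1]")
    f = a * force_gain(element, path_length)
    if element.passive_enabled and element.active:
        lf = fiber_length(element, path_length)
        if lf > 0:
            f += element.f_max * passive_force_length(lf / element.l_opt)
    return f


def deactivate_supraspinatus(model) -> "object":
    """Set every supraspinatus element inactive (zero force, zero
    equilibrium columns).  Idempotent; warns when absent."""
    supra = [m for m in model.muscles if m.group == "supraspinatus"]
    if not supra:
        warnings.warn("model has no supraspinatus elements; nothing to deactivate",
                      RuntimeWarning, stacklevel=2)
        return model
    for m in supra:
        m.active = False
    return model
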