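"""Rigid-body frames (rotation + translation) in SI units.

The global convention used throughout the package is right-handed with
y up, x anterior and z lateral (right side).  All lengths are metres and
all angles radians; file interfaces convert from mm / degrees on load.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class Frame:
    """A pose: ``x_world = rotation @ x_local + translation``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if self.translation.shape != (3,):
            raise ValueError("translation must be a 3-vector")

    @staticmethod
    def identity() -> "Frame":
        return Frame()

    @staticmethod
    def from_rotvec(rotvec, translation=(0.0, 0.0, 0.0)) -> "Frame":
        return Frame(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                     np.asarray(translation, float))

    @staticmethod
    def from_axis_angle(axis, angle: float, translation=(0.0, 0.0, 0.0)) -> "Frame":
        axis = np.asarray(axis, float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("axis must be nonzero")
        return Frame.from_rotvec(axis / n * angle, translation)

    def compose(self, other: "Frame") -> "Frame":
        """self ∘ other: apply ``other`` in this frame's coordinates."""
        return Frame(self.rotation @ other.rotation,
                     self.rotation @ other.translation + self.translation)

    def __matmul__(self, other: "Frame") -> "Frame":
        return self.compose(other)

    def inverse(self) -> "Frame":
        rt = self.rotation.T
        return Frame(rt, -rt @ self.translation)

    def transform_point(self, point) -> np.ndarray:
        return self.rotation @ np.asarray(point, float) + self.translation

    def transform_points(self, points) -> np.ndarray:
        pts = np.asarray(points, float)
        return pts @ self.rotation.T + self.translation

    def is_orthonormal(self, tol: float = _ORTHO_TOL) -> bool:
        r = self.rotation
        return (np.allclose(r.T @ r, np.eye(3), atol=10 * tol)
                and abs(np.linalg.det(r) - 1.0) <= tol * 10)


def rotation_about(axis, angle: float) -> np.ndarray:
    """Rotation matrix about a unit ``axis`` by ``angle`` (radians)."""
    axis = np.asarray(axis, float)
    return Rotation.from_rotvec(axis * angle).as_matrix()
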