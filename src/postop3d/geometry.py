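"""Planes and 6-DOF rigid transforms in world millimetres.

An osteotomy is represented as an infinite plane (center point + unit
normal); fragment repositioning as a rigid transform stored as a 4x4
homogeneous matrix whose rotation part is a proper rotation (det = +1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MisuseError


def unit(v, tol: float = 1e-12) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < tol:
        raise MisuseError("cannot normalize a near-zero vector")
    return v / n


def angle_between_deg(a, b) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    ua, ub = unit(a), unit(b)
    return float(np.degrees(np.arccos(np.clip(np.dot(ua, ub), -1.0, 1.0))))


@dataclass
class Plane:
    """Infinite plane: a point on it (``center``) and a unit ``normal``, mm."""

    center: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            self.normal = unit(self.normal)

    def signed_distance(self, points) -> np.ndarray:
        """Signed distance of points (..., 3) along the normal (mm)."""
        p = np.asarray(points, dtype=float)
        return (p - self.center) @ self.normal

    def project(self, points) -> np.ndarray:
        """Orthogonal projection of points onto the plane."""
        p = np.asarray(points, dtype=float)
        d = self.signed_distance(p)
        return p - np.multiply.outer(d, self.normal)

    def flipped(self) -> "Plane":
        return Plane(self.center.copy(), -self.normal)

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "normal": self.normal.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Plane":
        return cls(np.array(d["center"]), np.array(d["normal"]))


@dataclass
class RigidTransform:
    """Proper rigid transform as a 4x4 homogeneous matrix (mm)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise MisuseError("rigid transform matrix must be 4x4")
        R = m[:3, :3]
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6:
            raise MisuseError("rotation part must be orthonormal")
        if np.linalg.det(R) < 0:
            raise MisuseError("rotation part must have det = +1 (no reflections)")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
            raise MisuseError("last row must be (0, 0, 0, 1)")
        self.matrix = m

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R, t) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(R, dtype=float)
        m[:3, 3] = np.asarray(t, dtype=float).reshape(3)
        return cls(m)

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, center=(0, 0, 0),
                        translation=(0, 0, 0)) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` through ``center``,
        followed by ``translation``."""
        axis = unit(axis)
        a = np.radians(angle_deg)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        c = np.asarray(center, dtype=float).reshape(3)
        t = c - R @ c + np.asarray(translation, dtype=float).reshape(3)
        return cls.from_rotation_translation(R, t)

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls.from_rotation_translation(np.eye(3), t)

    # -- algebra ------------------------------------------------------------

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, vectors) -> np.ndarray:
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        m = np.eye(4)
        m[:3, :3] = Rt
        m[:3, 3] = -Rt @ self.translation
        return RigidTransform(m)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation in degrees."""
        c = (np.trace(self.rotation) - 1) / 2
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["matrix"]))
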