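"""Rigid-body transforms for multi-view point-cloud registration.

The camera-to-platform mapping is a proper rigid transform ``p' = R p + T``
with the rotation composed from per-axis Euler rotations in the fixed order

    R = RMq(delta) @ RMr(epsilon) @ RMs(lambda)

where ``RMq`` rotates about the first axis, ``RMr`` about the second and
``RMs`` about the third.  Angles are in radians; coordinates in metres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "EulerAngles",
    "RigidTransform",
    "rotation_from_angles",
    "apply_transform",
    "merge_views",
    "rotation_angle_between",
]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class EulerAngles:
    """Euler angles (radians) about the first, second and third axis."""

    delta: float
    epsilon: float
    lambda_: float

    def __post_init__(self) -> None:
        for name in ("delta", "epsilon", "lambda_"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")


def _rot_q(delta: float) -> np.ndarray:
    c, s = np.cos(delta), np.sin(delta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_r(epsilon: float) -> np.ndarray:
    c, s = np.cos(epsilon), np.sin(epsilon)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_s(lambda_: float) -> np.ndarray:
    c, s = np.cos(lambda_), np.sin(lambda_)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_from_angles(angles: EulerAngles | tuple[float, float, float]) -> np.ndarray:
    """Rotation matrix ``RMq @ RMr @ RMs`` for the given Euler angles."""
    if not isinstance(angles, EulerAngles):
        angles = EulerAngles(*angles)
    return _rot_q(angles.delta) @ _rot_r(angles.epsilon) @ _rot_s(angles.lambda_)


def _validate_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3) or not np.all(np.isfinite(rotation)):
        raise InvalidParameterError("rotation must be a finite 3x3 matrix")
    if not np.allclose(rotation.T @ rotation, np.eye(3), atol=_ORTHO_TOL):
        raise InvalidParameterError("rotation is not orthonormal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=_ORTHO_TOL):
        raise InvalidParameterError("rotation determinant is not +1 (improper rotation)")
    return rotation


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: ``p' = rotation @ p + translation``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _validate_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise InvalidParameterError("translation must be finite")
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_angles(
        cls,
        angles: EulerAngles | tuple[float, float, float],
        translation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        return cls(rotation_from_angles(angles), np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        single = points.ndim == 1
        pts = np.atleast_2d(points)
        if pts.shape[1] != 3:
            raise InvalidParameterError(f"points must be (n, 3), got {points.shape}")
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        r_inv = self.rotation.T
        return RigidTransform(r_inv, -r_inv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    # -- serialization (row-major 3x3 + 3-vector) --------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": [[float(v) for v in row] for row in self.rotation],
            "translation": [float(v) for v in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"], dtype=float), np.array(d["translation"], dtype=float))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RigidTransform":
        return cls.from_dict(json.loads(s))


def apply_transform(points: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Apply ``p' = R p + T`` to every point of a cloud."""
    if not isinstance(transform, RigidTransform):
        raise InvalidParameterError("transform must be a RigidTransform")
    return transform.apply(points)


def merge_views(views: list[np.ndarray], transforms: list[RigidTransform]) -> np.ndarray:
    """Map each view into the global frame and concatenate.

    Output point count equals the sum of the view counts; per-view point
    order is preserved.
    """
    if len(views) != len(transforms):
        raise InvalidParameterError(
            f"{len(views)} views but {len(transforms)} transforms"
        )
    if not views:
        raise InvalidParameterError("at least one view is required")
    return np.vstack([apply_transform(v, t) for v, t in zip(views, transforms)])


def rotation_angle_between(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic angle (radians) between two rotation matrices."""
    cos = (np.trace(np.asarray(r1).T @ np.asarray(r2)) - 1.0) / 2.0
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))
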