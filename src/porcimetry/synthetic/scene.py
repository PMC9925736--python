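"""Pen scenes and the three-camera rig with its reference cube.

A scene is the pig cloud plus floor, railing-bar and sparse-noise points,
each point carrying a ground-truth label so the filtering stages can be
scored exactly.  The rig holds three view poses (top/left/right) and the
pose of a calibration cube; rendering a view applies the inverse pose, so
merging the views with the true poses reproduces the scene to numerical
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidParameterError
from ..geometry import RigidTransform, apply_transform
from .pig import PigShapeParams

__all__ = [
    "LABELS",
    "RailingBar",
    "SceneSpec",
    "CameraRig",
    "compose_scene",
    "default_rig",
    "render_views",
    "sample_cube_cloud",
]

LABELS = {"pig": 0, "floor": 1, "railing": 2, "noise": 3}


@dataclass(frozen=True)
class RailingBar:
    """Axis-aligned cylindrical bar from ``start`` to ``end``."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float = 0.02


@dataclass(frozen=True)
class SceneSpec:
    """Counts, noise level and layout of a synthetic pen scene."""

    pig: PigShapeParams | None = None
    floor_elevation: float = 0.0
    railing_segments: tuple[RailingBar, ...] | None = None  # None -> two auto bars
    # floor count chosen so floor and pig surface sampling densities are
    # comparable (a depth sensor samples all surfaces at similar density)
    n_pig_points: int = 20_000
    n_floor_points: int = 12_000
    n_railing_points: int = 800
    n_noise_points: int = 200
    noise_sd: float = 0.002
    margin: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pig_points", "n_floor_points", "n_railing_points", "n_noise_points"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


def _default_railings(pig_cloud: np.ndarray, spec: SceneSpec) -> tuple[RailingBar, ...]:
    """Two horizontal bars parallel to x at the pig's flank height."""
    x_lo, x_hi = pig_cloud[:, 0].min() - 0.3, pig_cloud[:, 0].max() + 0.3
    y_off = pig_cloud[:, 1].max() + 0.12
    z_bar = float(np.median(pig_cloud[:, 2]))
    return (
        RailingBar((x_lo, -y_off, z_bar), (x_hi, -y_off, z_bar)),
        RailingBar((x_lo, y_off, z_bar), (x_hi, y_off, z_bar)),
    )


def _sample_bar(bar: RailingBar, n: int, rng) -> np.ndarray:
    start = np.asarray(bar.start, dtype=float)
    end = np.asarray(bar.end, dtype=float)
    axis = end - start
    length = np.linalg.norm(axis)
    if length == 0:
        raise InvalidParameterError("railing bar has zero length")
    axis = axis / length
    # orthonormal frame around the bar axis
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    s = rng.uniform(0.0, length, n)
    ang = rng.uniform(0.0, 2.0 * np.pi, n)
    return (
        start
        + np.outer(s, axis)
        + bar.radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    )


def compose_scene(pig_cloud: np.ndarray, spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Assemble pig + floor + railings + sparse noise with per-point labels.

    Floor points scatter vertically with a normal deviate truncated at
    ±4·noise_sd about ``z = floor_elevation``; label counts match the spec
    counts exactly.
    """
    pig_cloud = np.atleast_2d(np.asarray(pig_cloud, dtype=float))
    rng = np.random.default_rng(spec.seed)
    parts = [pig_cloud]
    labels = [np.full(len(pig_cloud), LABELS["pig"], dtype=int)]

    x_lo, x_hi = pig_cloud[:, 0].min(), pig_cloud[:, 0].max()
    y_lo, y_hi = pig_cloud[:, 1].min(), pig_cloud[:, 1].max()
    z_hi = pig_cloud[:, 2].max()
    m = spec.margin

    if spec.n_floor_points:
        fx = rng.uniform(x_lo - m, x_hi + m, spec.n_floor_points)
        fy = rng.uniform(y_lo - m, y_hi + m, spec.n_floor_points)
        if spec.noise_sd > 0:
            fz = spec.floor_elevation + np.clip(
                rng.normal(0.0, spec.noise_sd, spec.n_floor_points),
                -4 * spec.noise_sd,
                4 * spec.noise_sd,
            )
        else:
            fz = np.full(spec.n_floor_points, spec.floor_elevation)
        parts.append(np.column_stack([fx, fy, fz]))
        labels.append(np.full(spec.n_floor_points, LABELS["floor"], dtype=int))

    if spec.n_railing_points:
        bars = spec.railing_segments or _default_railings(pig_cloud, spec)
        counts = np.full(len(bars), spec.n_railing_points // len(bars))
        counts[: spec.n_railing_points - counts.sum()] += 1
        for bar, cnt in zip(bars, counts):
            if cnt:
                parts.append(_sample_bar(bar, int(cnt), rng))
                labels.append(np.full(int(cnt), LABELS["railing"], dtype=int))

    if spec.n_noise_points:
        nx = rng.uniform(x_lo - m, x_hi + m, spec.n_noise_points)
        ny = rng.uniform(y_lo - m, y_hi + m, spec.n_noise_points)
        nz = rng.uniform(spec.floor_elevation, z_hi + 0.3, spec.n_noise_points)
        parts.append(np.column_stack([nx, ny, nz]))
        labels.append(np.full(spec.n_noise_points, LABELS["noise"], dtype=int))

    return np.vstack(parts), np.concatenate(labels)


@dataclass(frozen=True)
class CameraRig:
    """Three view poses (top, left, right) plus the reference-cube pose.

    A pose maps camera coordinates into the global platform frame, so a
    camera's view of the scene is the scene transformed by the inverse
    pose.  Pose rotations are validated (orthonormal, det +1) by
    ``RigidTransform``.
    """

    poses: tuple[RigidTransform, RigidTransform, RigidTransform]
    cube_size: float = 0.4
    cube_pose: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self) -> None:
        if len(self.poses) != 3:
            raise InvalidParameterError("a rig has exactly three view poses")
        if not self.cube_size > 0:
            raise InvalidParameterError("cube_size must be positive")


def default_rig(cube_size: float = 0.4) -> CameraRig:
    """Top/left/right poses within the depth camera's 0.5–4.5 m range."""
    top = RigidTransform.from_angles((0.05, 0.10, 0.08), (0.5, 0.1, 2.0))
    left = RigidTransform.from_angles((0.35, -0.10, 0.12), (0.5, -1.6, 0.9))
    right = RigidTransform.from_angles((-0.30, 0.15, -0.20), (0.5, 1.6, 0.9))
    cube_pose = RigidTransform.from_angles((0.0, 0.0, 0.0), (0.5, 0.0, cube_size / 2.0))
    return CameraRig(poses=(top, left, right), cube_size=cube_size, cube_pose=cube_pose)


def sample_cube_cloud(
    cube_pose: RigidTransform,
    cube_size: float,
    n: int = 3000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sample points uniformly on all six faces of the reference cube."""
    if n < 60:
        raise InvalidParameterError("need at least 60 cube points")
    rng = np.random.default_rng(seed)
    half = cube_size / 2.0
    face = rng.integers(0, 6, n)
    u = rng.uniform(-half, half, n)
    v = rng.uniform(-half, half, n)
    pts = np.empty((n, 3))
    axis = face // 2  # 0:x, 1:y, 2:z
    sign = np.where(face % 2 == 0, 1.0, -1.0)
    for a in range(3):
        mask = axis == a
        others = [i for i in range(3) if i != a]
        pts[mask, a] = sign[mask] * half
        pts[mask, others[0]] = u[mask]
        pts[mask, others[1]] = v[mask]
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    return apply_transform(pts, cube_pose)


def render_views(
    scene: np.ndarray,
    rig: CameraRig,
    n_cube_points: int = 3000,
    cube_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Render the scene and the reference cube into each camera's frame.

    Each view is the scene (and cube) transformed by the inverse of that
    view's pose; per-view cube noise is drawn independently in camera
    coordinates.  Returns ``(scene_views, cube_views)``.
    """
    scene = np.atleast_2d(np.asarray(scene, dtype=float))
    cube_global = sample_cube_cloud(rig.cube_pose, rig.cube_size, n_cube_points, 0.0, seed)
    views, cube_views = [], []
    for i, pose in enumerate(rig.poses):
        inv = pose.inverse()
        views.append(inv.apply(scene))
        cube = inv.apply(cube_global)
        if cube_noise_sd > 0:
            sub = np.random.default_rng((seed, i))
            cube = cube + sub.normal(0.0, cube_noise_sd, cube.shape)
        cube_views.append(cube)
    return views, cube_views
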