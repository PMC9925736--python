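"""Scene filtering: pass-through crop, RANSAC floor removal, radius outlier
removal.

The pipeline isolates the pig from a registered pen scene in three passes:
an axis-aligned pass-through crop to the viewing region (which also removes
the railing bars, whose positions are fixed by the pen geometry), RANSAC
segmentation of the dominant plane (the concrete floor), and a radius
outlier filter that drops points with fewer than ``h`` neighbours within
radius ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidParameterError, NoPlaneFoundError

__all__ = [
    "PassThroughBounds",
    "RansacPlaneParams",
    "RadiusFilterParams",
    "pass_through",
    "remove_floor",
    "radius_outlier_removal",
]


@dataclass(frozen=True)
class PassThroughBounds:
    """Closed per-axis intervals in metres; ``None`` leaves an axis open."""

    x: tuple[float, float] | None = None
    y: tuple[float, float] | None = None
    z: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            iv = getattr(self, name)
            if iv is not None and not iv[0] <= iv[1]:
                raise InvalidParameterError(f"{name} interval has min > max")


@dataclass(frozen=True)
class RansacPlaneParams:
    """RANSAC plane segmentation parameters."""

    distance_threshold: float = 0.01  # metres
    n_iterations: int = 1000
    seed: int = 0
    min_inlier_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not self.distance_threshold > 0:
            raise InvalidParameterError("distance_threshold must be positive")
        if self.n_iterations < 1:
            raise InvalidParameterError("n_iterations must be >= 1")
        if not 0 <= self.min_inlier_fraction <= 1:
            raise InvalidParameterError("min_inlier_fraction must be in [0, 1]")


@dataclass(frozen=True)
class RadiusFilterParams:
    """Radius outlier removal: keep points with >= ``min_neighbors``
    strict neighbours (the point itself excluded) within ``radius``."""

    radius: float = 0.03  # metres
    min_neighbors: int = 5

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise InvalidParameterError("radius must be positive")
        if self.min_neighbors < 1:
            raise InvalidParameterError("min_neighbors must be >= 1")


def pass_through(cloud: np.ndarray, bounds: PassThroughBounds) -> np.ndarray:
    """Keep exactly the points inside all supplied intervals, in order."""
    pts = np.atleast_2d(np.asarray(cloud, dtype=float))
    if pts.size == 0:
        return pts.reshape(0, 3)
    mask = np.ones(len(pts), dtype=bool)
    for axis, iv in enumerate((bounds.x, bounds.y, bounds.z)):
        if iv is not None:
            mask &= (pts[:, axis] >= iv[0]) & (pts[:, axis] <= iv[1])
    return pts[mask]


def _plane_from_three(p0, p1, p2):
    normal = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        return None
    normal = normal / norm
    return normal, float(normal @ p0)


def remove_floor(
    cloud: np.ndarray, params: RansacPlaneParams = RansacPlaneParams()
) -> tuple[np.ndarray, tuple[np.ndarray, float]]:
    """Remove the dominant RANSAC plane (the floor).

    Random 3-point plane hypotheses are scored by inlier count (distance
    <= ``distance_threshold``); the winner is refined by a least-squares
    refit on its inliers.  Returns ``(pig_cloud, (unit_normal, offset))``
    with the plane in normalized form ``normal · p = offset`` and the
    normal oriented upwards.  Deterministic for a fixed seed.
    """
    pts = np.atleast_2d(np.asarray(cloud, dtype=float))
    n = len(pts)
    if n < 3:
        raise InvalidParameterError(f"need at least 3 points, got {n}")
    rng = np.random.default_rng(params.seed)

    best_count, best_plane = -1, None
    for _ in range(params.n_iterations):
        i, j, k = rng.choice(n, size=3, replace=False)
        plane = _plane_from_three(pts[i], pts[j], pts[k])
        if plane is None:
            continue
        normal, offset = plane
        count = int(np.count_nonzero(np.abs(pts @ normal - offset) <= params.distance_threshold))
        if count > best_count:
            best_count, best_plane = count, plane
    if best_plane is None or best_count < params.min_inlier_fraction * n:
        raise NoPlaneFoundError(
            f"best plane has {max(best_count, 0)}/{n} inliers, below "
            f"min_inlier_fraction={params.min_inlier_fraction}"
        )

    # least-squares refit on the consensus set
    normal, offset = best_plane
    inliers = np.abs(pts @ normal - offset) <= params.distance_threshold
    sub = pts[inliers]
    centroid = sub.mean(axis=0)
    _, _, vt = np.linalg.svd(sub - centroid, full_matrices=False)
    normal = vt[-1]
    if normal[2] < 0:
        normal = -normal
    offset = float(normal @ centroid)
    inliers = np.abs(pts @ normal - offset) <= params.distance_threshold
    return pts[~inliers], (normal, offset)


def radius_outlier_removal(
    cloud: np.ndarray, params: RadiusFilterParams = RadiusFilterParams()
) -> np.ndarray:
    """Keep exactly the points with >= ``min_neighbors`` neighbours within
    ``radius`` (the query point itself is not counted), order preserved."""
    pts = np.atleast_2d(np.asarray(cloud, dtype=float))
    if len(pts) == 0:
        return pts.reshape(0, 3)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, params.radius, return_length=True) - 1
    return pts[counts >= params.min_neighbors]
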