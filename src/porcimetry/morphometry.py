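"""Body-size measurement from a cleaned, registered pig point cloud.

Four quantities are measured, all in metres:

* **body length** — arc length of the dorsal ridge, integrated along the
  fitted ridge curve (``∫ √(dx² + dy² + dz²)``);
* **withers height** — height above the floor plane of the *second* local
  maximum of the dorsal height profile counted from the anterior end (the
  first maximum is the head/ears);
* **abdominal width** — lateral extent of the body slice at the position of
  greatest breadth between the fore- and hind limbs;
* **abdominal circumference** — arc length ``∫₀^{2π} √(f(θ)² + f'(θ)²) dθ``
  of a periodic cubic b-spline ``ρ = f(θ)`` fitted to the abdominal slice in
  polar coordinates about the slice centroid.

The polar angle uses the two-branch rule

    θ = arctan(−(y−y₀)/(z−z₀)) + π/2   if y ≥ y₀
    θ = arctan(−(y−y₀)/(z−z₀)) + 3π/2  if y < y₀

mapped into [0, 2π).  This rule is not the continuous counter-clockwise
angle: it sends each (y, z) quadrant of the slice to a different angular
quadrant.  It is nevertheless a bijection on the slice, and for centrally
symmetric cross-sections (ρ(φ+π) = ρ(φ), which superellipse-like animal
sections satisfy) the induced radius function — and therefore the
circumference integral — is unchanged.

Clouds are assumed registered into the global frame (z vertical up).  The
body axis is identified as the principal direction of the cloud's horizontal
spread; the anterior end is the end whose nearest height-profile maximum is
higher (the head).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate
from scipy.integrate import simpson
from scipy.signal import find_peaks

from .errors import (
    DegenerateGeometryError,
    InsufficientCoverageError,
    InsufficientDataError,
    InvalidParameterError,
    WithersNotFoundError,
)
from .geometry import RigidTransform

__all__ = [
    "PlaneFit",
    "PolarSlice",
    "ClosedCurve",
    "MorphometryResult",
    "MorphometryConfig",
    "fit_longitudinal_plane",
    "orient_pig_cloud",
    "body_length",
    "withers_height",
    "locate_abdominal_slice",
    "body_width",
    "to_polar",
    "fit_closed_curve",
    "abdominal_circumference",
    "measure_pig",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PlaneFit:
    """Least-squares plane ``z = a0·x + a1·y + a2`` with residual ``S``."""

    a0: float
    a1: float
    a2: float
    residual: float

    def heights_above(self, points: np.ndarray) -> np.ndarray:
        """Perpendicular distance of each point above the plane."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        normal = np.array([-self.a0, -self.a1, 1.0])
        normal /= np.linalg.norm(normal)
        offset = self.a2 * normal[2]
        return points @ normal - offset


@dataclass(frozen=True)
class PolarSlice:
    """Abdominal slice in polar coordinates about its centroid pole."""

    pole: np.ndarray  # (y0, z0)
    rho: np.ndarray
    theta: np.ndarray


class ClosedCurve:
    """Periodic cubic b-spline radius function ``f: θ ∈ [0, 2π) → ρ``."""

    def __init__(self, tck, theta_origin: float):
        self._tck = tck
        self._t0 = float(theta_origin)

    def _wrap(self, theta):
        theta = np.asarray(theta, dtype=float)
        return self._t0 + np.mod(theta - self._t0, _TWO_PI)

    def __call__(self, theta):
        return interpolate.splev(self._wrap(theta), self._tck)

    def derivative(self, theta):
        return interpolate.splev(self._wrap(theta), self._tck, der=1)


@dataclass(frozen=True)
class MorphometryResult:
    """Body measurements in metres, with the slice position used."""

    length: float
    height: float
    width: float
    abdominal_circumference: float
    slice_position: float

    def __post_init__(self) -> None:
        for name in ("length", "height", "width", "abdominal_circumference"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        # a closed curve's maximum chord cannot exceed half its perimeter
        if self.width > self.abdominal_circumference / 2.0 + 1e-9:
            raise InvalidParameterError(
                "width exceeds half the circumference (impossible closed section)"
            )

    def to_dict(self) -> dict:
        return {
            "length_m": float(self.length),
            "height_m": float(self.height),
            "width_m": float(self.width),
            "abdominal_circumference_m": float(self.abdominal_circumference),
            "slice_position_m": float(self.slice_position),
        }


@dataclass(frozen=True)
class MorphometryConfig:
    """Tunable measurement parameters (metres unless noted)."""

    bin_width: float = 0.02          # axial bin for profiles and the ridge
    smooth_bins: int = 3             # moving-maximum window for the profile
    peak_prominence: float = 0.015   # minimum prominence of profile maxima
    slab_thickness: float = 0.02     # abdominal slice thickness
    ridge_top_band: float = 0.01     # vertical band defining ridge points
    spline_smoothing: float | None = None  # None -> scaled default
    n_quadrature: int = 4097         # Simpson sample count (odd)
    min_coverage: float = 1.5 * np.pi  # minimum slice angular coverage (rad)


# ---------------------------------------------------------------------------
# plane fitting


def fit_longitudinal_plane(points: np.ndarray) -> PlaneFit:
    """Least-squares minimizer of ``S = Σ (a0·xi + a1·yi + a2 − zi)²``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 3:
        raise DegenerateGeometryError("need at least 3 points with 3 coordinates")
    a = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    coef, _, rank, _ = np.linalg.lstsq(a, pts[:, 2], rcond=None)
    if rank < 3:
        raise DegenerateGeometryError("points are collinear (plane is not determined)")
    residual = float(np.sum((a @ coef - pts[:, 2]) ** 2))
    return PlaneFit(float(coef[0]), float(coef[1]), float(coef[2]), residual)


def _heights_above_floor(points: np.ndarray, floor) -> np.ndarray:
    """Height of each point above the floor plane.

    ``floor`` may be None (z = 0), a ``PlaneFit``, or a ``(normal, offset)``
    pair with the plane defined by ``normal · p = offset``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if floor is None:
        return pts[:, 2].copy()
    if isinstance(floor, PlaneFit):
        return floor.heights_above(pts)
    normal, offset = floor
    normal = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(normal)
    normal, offset = normal / norm, float(offset) / norm
    if normal[2] < 0:  # orient the normal upwards
        normal, offset = -normal, -offset
    return pts @ normal - offset


# ---------------------------------------------------------------------------
# orientation and profiles


def _axial_bins(x: np.ndarray, bin_width: float):
    lo, hi = float(np.min(x)), float(np.max(x))
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + np.arange(n_bins + 1) * bin_width
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    centers = edges[:-1] + bin_width / 2.0
    return idx, centers, n_bins


def _height_profile(points, floor, config: MorphometryConfig, min_bin_points: int = 3):
    """(bin centers, smoothed per-bin maximum height) along the body axis."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    h = _heights_above_floor(pts, floor)
    idx, centers, n_bins = _axial_bins(pts[:, 0], config.bin_width)
    prof = np.full(n_bins, -np.inf)
    np.maximum.at(prof, idx, h)
    counts = np.bincount(idx, minlength=n_bins)
    valid = counts >= min_bin_points
    centers, prof = centers[valid], prof[valid]
    if len(prof) == 0:
        raise InsufficientDataError("no populated bins along the body axis")
    # moving maximum stabilises the extremum structure against bin jitter
    w = max(int(config.smooth_bins), 1)
    if w > 1 and len(prof) >= w:
        from numpy.lib.stride_tricks import sliding_window_view

        pad = w // 2
        padded = np.pad(prof, pad, mode="edge")
        prof = sliding_window_view(padded, w).max(axis=1)[: len(centers)]
    return centers, prof


def _profile_peaks(centers, prof, prominence):
    peaks, _ = find_peaks(prof, prominence=prominence)
    return peaks


def orient_pig_cloud(
    points: np.ndarray,
    floor=None,
    config: MorphometryConfig = MorphometryConfig(),
) -> tuple[np.ndarray, RigidTransform]:
    """Rotate about the vertical so the body axis is x, anterior at low x.

    The body axis is the principal direction of the horizontal (x, y)
    spread; the anterior end is the end whose nearest height-profile local
    maximum is the higher one (the head overtops the withers).  Returns the
    oriented cloud and the rigid transform that was applied.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise InsufficientDataError("need at least 3 points to orient")
    center = pts[:, :2].mean(axis=0)
    xy = pts[:, :2] - center
    cov = xy.T @ xy / len(xy)
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]  # largest-spread horizontal direction
    yaw = np.arctan2(axis[1], axis[0])
    rot = RigidTransform.from_angles((0.0, 0.0, -yaw))
    shift = RigidTransform(np.eye(3), np.array([-center[0], -center[1], 0.0]))
    transform = rot.compose(shift)
    oriented = transform.apply(pts)

    try:
        centers, prof = _height_profile(oriented, floor, config)
        peaks = _profile_peaks(centers, prof, config.peak_prominence)
    except InsufficientDataError:
        peaks = np.array([], dtype=int)
    if len(peaks) >= 2 and prof[peaks[-1]] > prof[peaks[0]]:
        flip = RigidTransform.from_angles((0.0, 0.0, np.pi))
        transform = flip.compose(transform)
        oriented = flip.apply(oriented)
    return oriented, transform


# ---------------------------------------------------------------------------
# body length


def _ridge_samples_surface(pts, config: MorphometryConfig):
    idx, centers, n_bins = _axial_bins(pts[:, 0], config.bin_width)
    samples = []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() < 2:
            continue
        sub = pts[mask]
        top = sub[:, 2] >= sub[:, 2].max() - config.ridge_top_band
        samples.append(sub[top].mean(axis=0))
    if len(samples) < 4:
        raise InsufficientDataError("too few ridge bins to fit the length curve")
    ridge = np.array(samples)
    ridge = ridge[np.argsort(ridge[:, 0])]
    # project onto the longitudinal section: the ridge of a bilaterally
    # symmetric body lies in the vertical plane through the body axis, and
    # projecting removes the lateral jitter of the per-bin band means
    ridge[:, 1] = np.median(ridge[:, 1])
    # extend horizontally to the exact axial extremes (half-bin end bias)
    lo = np.array([pts[:, 0].min(), ridge[0, 1], ridge[0, 2]])
    hi = np.array([pts[:, 0].max(), ridge[-1, 1], ridge[-1, 2]])
    return np.vstack([lo, ridge, hi])


def _ridge_samples_bare(pts, config: MorphometryConfig):
    """Polyline through a bare ridge-curve cloud, following steep ends.

    Interior bins contribute their mean point; the two end bins are
    sub-binned vertically so near-vertical ridge segments (e.g. the ends of
    an arched back) are traversed rather than collapsed.
    """
    idx, centers, n_bins = _axial_bins(pts[:, 0], config.bin_width)
    counts = np.bincount(idx, minlength=n_bins)
    populated = np.flatnonzero(counts > 0)
    first, last = populated[0], populated[-1]

    interior = []
    for b in populated:
        if b in (first, last):
            continue
        interior.append(pts[idx == b].mean(axis=0))

    def end_segment(b):
        sub = pts[idx == b]
        z = sub[:, 2]
        if z.max() - z.min() <= 2 * config.bin_width:
            return [sub.mean(axis=0)]
        zi, _, nz = _axial_bins(z, config.bin_width / 2.0)
        seg = [sub[zi == k].mean(axis=0) for k in range(nz) if np.any(zi == k)]
        return sorted(seg, key=lambda p: p[2])

    seg_lo, seg_hi = end_segment(first), end_segment(last)
    if interior:
        if abs(seg_lo[0][2] - interior[0][2]) < abs(seg_lo[-1][2] - interior[0][2]):
            seg_lo = seg_lo[::-1]  # point nearest the interior goes last
        if abs(seg_hi[-1][2] - interior[-1][2]) < abs(seg_hi[0][2] - interior[-1][2]):
            seg_hi = seg_hi[::-1]
    poly = seg_lo + interior + seg_hi
    # exact axial extreme points bound the curve ends
    lo_pt = pts[np.argmin(pts[:, 0])]
    hi_pt = pts[np.argmax(pts[:, 0])]
    return np.vstack([lo_pt, np.array(poly), hi_pt])


def body_length(points: np.ndarray, config: MorphometryConfig = MorphometryConfig()) -> float:
    """Arc length of the dorsal ridge curve.

    The ridge is extracted per axial bin (top vertical band for surface
    clouds; bin means for bare ridge-curve clouds, detected by their small
    lateral spread), fitted with a smoothing parametric cubic spline, and
    integrated by composite Simpson quadrature.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 500:
        raise InsufficientDataError(
            f"need at least 500 points to extract a ridge, got {len(pts)}"
        )
    extent = pts[:, 0].max() - pts[:, 0].min()
    if extent <= 0:
        raise InsufficientDataError("cloud has no axial extent")

    idx, _, n_bins = _axial_bins(pts[:, 0], config.bin_width)
    spreads = []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() >= 3:
            spreads.append(np.ptp(pts[mask, 1]))
    bare = spreads and np.median(spreads) < 0.03 * extent

    if bare:
        poly = _ridge_samples_bare(pts, config)
        deltas = np.diff(poly, axis=0)
        return float(np.sum(np.linalg.norm(deltas, axis=1)))

    ridge = _ridge_samples_surface(pts, config)
    m = len(ridge)
    s = config.spline_smoothing if config.spline_smoothing is not None else m * (1e-3) ** 2
    tck, u = interpolate.splprep(list(ridge.T), s=s, k=min(3, m - 1))
    uu = np.linspace(0.0, 1.0, config.n_quadrature)
    dx, dy, dz = interpolate.splev(uu, tck, der=1)
    speed = np.sqrt(np.asarray(dx) ** 2 + np.asarray(dy) ** 2 + np.asarray(dz) ** 2)
    return float(simpson(speed, x=uu))


# ---------------------------------------------------------------------------
# withers height


def withers_height(
    points: np.ndarray,
    floor=None,
    config: MorphometryConfig = MorphometryConfig(),
) -> float:
    """Height of the withers above the floor plane.

    The dorsal height profile (per-bin maxima, moving-maximum smoothed) is
    scanned for local maxima; the second maximum counted from the anterior
    end — the end whose nearest maximum is the higher one — is the withers.
    """
    centers, prof = _height_profile(points, floor, config)
    peaks = _profile_peaks(centers, prof, config.peak_prominence)
    if len(peaks) < 2:
        raise WithersNotFoundError(
            f"height profile has {len(peaks)} local maxima; need head and withers"
        )
    if prof[peaks[-1]] > prof[peaks[0]]:
        peaks = peaks[::-1]  # anterior end is at high x; scan from there
    return float(prof[peaks[1]])


# ---------------------------------------------------------------------------
# abdominal slice


def _limb_bounds(pts, heights, idx, centers, n_bins):
    """x-interval strictly between the fore- and hind-limb positions.

    Limb bins are those whose lowest point reaches well below the belly
    line.  Returns None when no limbs flank the abdomen (e.g. a bare
    cylinder), in which case the central body is searched instead.
    """
    min_h = np.full(n_bins, np.inf)
    np.minimum.at(min_h, idx, heights)
    counts = np.bincount(idx, minlength=n_bins)
    valid = counts >= 5
    if valid.sum() < 3:
        return None
    belly = np.median(min_h[valid])
    if belly <= 0:
        return None
    leg = valid & (min_h < 0.4 * belly)
    mid = np.median(pts[:, 0])
    fore = [c for c, is_leg in zip(centers, leg) if is_leg and c < mid]
    hind = [c for c, is_leg in zip(centers, leg) if is_leg and c >= mid]
    if not fore or not hind:
        return None
    return max(fore), min(hind)


def locate_abdominal_slice(
    points: np.ndarray,
    floor=None,
    config: MorphometryConfig = MorphometryConfig(),
) -> tuple[np.ndarray, float]:
    """Slice of greatest lateral extent strictly between the limbs.

    Returns the points within a slab of ``config.slab_thickness`` at the
    widest axial position, and that position.  Ties (a body of uniform
    width) resolve to the lowest-x candidate.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 20:
        raise InsufficientDataError("too few points to locate the abdominal slice")
    heights = _heights_above_floor(pts, floor)
    idx, centers, n_bins = _axial_bins(pts[:, 0], config.bin_width)

    width = np.full(n_bins, -np.inf)
    y_min = np.full(n_bins, np.inf)
    y_max = np.full(n_bins, -np.inf)
    np.minimum.at(y_min, idx, pts[:, 1])
    np.maximum.at(y_max, idx, pts[:, 1])
    counts = np.bincount(idx, minlength=n_bins)
    ok = counts >= 5
    width[ok] = (y_max - y_min)[ok]

    bounds = _limb_bounds(pts, heights, idx, centers, n_bins)
    if bounds is None:
        span = np.ptp(pts[:, 0])
        lo = pts[:, 0].min() + 0.15 * span
        hi = pts[:, 0].max() - 0.15 * span
    else:
        lo = bounds[0] + config.bin_width
        hi = bounds[1] - config.bin_width
    candidate = ok & (centers > lo) & (centers < hi)
    if not np.any(candidate):
        candidate = ok
    if not np.any(candidate):
        raise InsufficientDataError("no populated axial bins for the slice search")
    best = np.flatnonzero(candidate)[np.argmax(width[candidate])]
    position = float(centers[best])
    mask = np.abs(pts[:, 0] - position) <= config.slab_thickness / 2.0
    if not np.any(mask):
        raise InsufficientDataError("abdominal slab is empty")
    return pts[mask], position


def body_width(slice_points: np.ndarray) -> float:
    """Lateral (y) extent of the abdominal slice."""
    pts = np.atleast_2d(np.asarray(slice_points, dtype=float))
    if pts.size == 0 or len(pts) < 2:
        raise InsufficientDataError("empty abdominal slice")
    return float(pts[:, 1].max() - pts[:, 1].min())


# ---------------------------------------------------------------------------
# polar conversion and the closed-curve circumference


def to_polar(slice_points: np.ndarray) -> PolarSlice:
    """Convert an abdominal slice to polar form about its centroid pole.

    Accepts (n, 3) clouds (the x column is dropped) or (n, 2) (y, z) data.
    A point coincident with the pole keeps ρ = 0 and is assigned θ = 0.
    """
    pts = np.atleast_2d(np.asarray(slice_points, dtype=float))
    yz = pts[:, 1:3] if pts.shape[1] == 3 else pts
    if yz.shape[1] != 2:
        raise InvalidParameterError("slice must have 2 or 3 coordinate columns")
    pole = yz.mean(axis=0)
    dy = yz[:, 0] - pole[0]
    dz = yz[:, 1] - pole[1]
    rho = np.hypot(dy, dz)
    with np.errstate(divide="ignore", invalid="ignore"):
        base = np.arctan(-dy / dz)
    theta = base + np.where(dy >= 0, np.pi / 2.0, 3.0 * np.pi / 2.0)
    theta = np.mod(theta, _TWO_PI)
    theta[rho == 0] = 0.0
    return PolarSlice(pole=pole, rho=rho, theta=theta)


def fit_closed_curve(
    polar: PolarSlice,
    smoothing: float | None = None,
    min_coverage: float = 1.5 * np.pi,
) -> ClosedCurve:
    """Periodic cubic b-spline fit of ρ(θ), bridging angular gaps.

    Requires at least 8 samples spanning at least ``min_coverage`` radians
    (default 270°); occluded sectors (railing shadow) are interpolated by
    the periodic spline.
    """
    theta = np.asarray(polar.theta, dtype=float)
    rho = np.asarray(polar.rho, dtype=float)
    if len(theta) < 8:
        raise InsufficientDataError(f"need at least 8 polar samples, got {len(theta)}")
    order = np.argsort(theta)
    theta, rho = theta[order], rho[order]
    gaps = np.diff(theta)
    wrap_gap = theta[0] + _TWO_PI - theta[-1]
    coverage = _TWO_PI - max(gaps.max(initial=0.0), wrap_gap)
    if coverage < min_coverage:
        raise InsufficientCoverageError(
            f"angular coverage {np.degrees(coverage):.1f} deg is below "
            f"{np.degrees(min_coverage):.1f} deg"
        )
    # merge duplicate angles (FITPACK needs strictly increasing abscissae)
    uniq, inverse = np.unique(np.round(theta / 1e-9).astype(np.int64), return_inverse=True)
    if len(uniq) < len(theta):
        theta_m = np.zeros(len(uniq))
        rho_m = np.zeros(len(uniq))
        counts = np.bincount(inverse)
        np.add.at(theta_m, inverse, theta)
        np.add.at(rho_m, inverse, rho)
        theta, rho = theta_m / counts, rho_m / counts
    if len(theta) < 8:
        raise InsufficientDataError("fewer than 8 distinct polar angles")

    t_ext = np.append(theta, theta[0] + _TWO_PI)
    r_ext = np.append(rho, rho[0])
    m = len(theta)
    s = smoothing if smoothing is not None else m * (3e-3) ** 2
    tck = interpolate.splrep(t_ext, r_ext, per=1, s=s, k=3)
    return ClosedCurve(tck, theta[0])


def abdominal_circumference(curve: ClosedCurve, n_quadrature: int = 4097) -> float:
    """Arc length ``∫₀^{2π} √(f(θ)² + f'(θ)²) dθ`` by composite Simpson."""
    if n_quadrature % 2 == 0:
        n_quadrature += 1
    theta = np.linspace(0.0, _TWO_PI, n_quadrature)
    f = np.asarray(curve(theta), dtype=float)
    fp = np.asarray(curve.derivative(theta), dtype=float)
    return float(simpson(np.sqrt(f**2 + fp**2), x=theta))


# ---------------------------------------------------------------------------
# full measurement


def measure_pig(
    points: np.ndarray,
    floor=None,
    orient: bool = True,
    config: MorphometryConfig = MorphometryConfig(),
) -> MorphometryResult:
    """Measure length, height, width and abdominal circumference.

    The cloud is first oriented (principal horizontal axis → x, anterior at
    low x) unless ``orient`` is False.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if orient:
        pts, _ = orient_pig_cloud(pts, floor, config)
    length = body_length(pts, config)
    height = withers_height(pts, floor, config)
    slice_pts, position = locate_abdominal_slice(pts, floor, config)
    width = body_width(slice_pts)
    curve = fit_closed_curve(
        to_polar(slice_pts),
        smoothing=config.spline_smoothing,
        min_coverage=config.min_coverage,
    )
    circumference = abdominal_circumference(curve, config.n_quadrature)
    return MorphometryResult(
        length=length,
        height=height,
        width=width,
        abdominal_circumference=circumference,
        slice_position=position,
    )
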