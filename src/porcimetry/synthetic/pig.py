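"""Parametric pig-shaped point clouds with analytic ground truth.

The body is a loft of superellipse cross-sections along a (possibly arched)
spine: at axial position ``t ∈ [0, 1]`` (anterior → posterior) the section
is ``|y/a(t)|^p + |(z − zc(t))/b(t)|^p = 1`` with half-width ``a``,
half-height ``b`` from the cross-section profile, and the section centre
``zc(t) = leg_stub_height + b(t) + arch(t)`` riding on the dorsal arch
``arch(t) = dorsal_curvature · sin(πt)``.  Four short vertical cylinders
form leg stubs, which gives the height profile its head/withers bimodality
and bounds the abdominal slice search.

Coordinate convention: x = body axis (anterior → posterior), y = lateral,
z = vertical up, floor at z = 0; all lengths in metres.

``body_length`` is the dorsal-ridge *arc* length; the generator solves for
the straight axial span that yields that arc, so ground truth always equals
the parameter.  All ground-truth values are obtained by dense numerical
integration of the parametric shape, independent of the sampled points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.signal import find_peaks

from ..errors import InvalidParameterError
from ..morphometry import MorphometryResult

__all__ = [
    "PigShapeParams",
    "cylinder_pig",
    "standard_pig",
    "generate_pig_cloud",
    "ground_truth_morphometry",
    "superellipse_perimeter",
]

_GRID = 20001  # dense parameter grid for ground-truth integration


@dataclass(frozen=True)
class PigShapeParams:
    """Parametric pig shape.

    ``cross_section_profile`` maps ``t ∈ [0, 1]`` (vectorized) to
    ``(half_width, half_height)`` in metres.  ``abdominal_max_half_width``
    must equal the profile's maximum half-width.
    """

    body_length: float
    cross_section_profile: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]
    withers_height: float
    abdominal_max_half_width: float
    leg_stub_height: float
    dorsal_curvature: float = 0.0
    section_exponent: float = 2.0
    leg_radius: float = 0.03
    leg_positions: tuple[float, float] = (0.22, 0.78)

    def __post_init__(self) -> None:
        for name in ("body_length", "withers_height", "abdominal_max_half_width"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.leg_stub_height < 0 or self.dorsal_curvature < 0:
            raise InvalidParameterError("leg_stub_height and dorsal_curvature must be >= 0")
        if not self.section_exponent > 0:
            raise InvalidParameterError("section_exponent must be positive")

    def profile(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hw, hh = self.cross_section_profile(np.asarray(t, dtype=float))
        return np.asarray(hw, dtype=float), np.asarray(hh, dtype=float)

    def arch(self, t: np.ndarray) -> np.ndarray:
        return self.dorsal_curvature * np.sin(np.pi * np.asarray(t, dtype=float))

    def top_height(self, t: np.ndarray) -> np.ndarray:
        """Dorsal ridge height above the floor at parameter ``t``."""
        _, hh = self.profile(t)
        return self.leg_stub_height + 2.0 * hh + self.arch(t)


def _ridge_arc(params: PigShapeParams, span: float, t: np.ndarray, ztop: np.ndarray) -> float:
    dx = span * np.diff(t)
    dz = np.diff(ztop)
    return float(np.sum(np.hypot(dx, dz)))


def solve_axial_span(params: PigShapeParams) -> float:
    """Straight axial span whose dorsal ridge arc equals ``body_length``."""
    t = np.linspace(0.0, 1.0, _GRID)
    ztop = params.top_height(t)
    vertical = float(np.sum(np.abs(np.diff(ztop))))
    if vertical >= params.body_length:
        raise InvalidParameterError(
            "body_length is shorter than the dorsal height variation alone"
        )
    if vertical == 0.0:
        return params.body_length
    f = lambda span: _ridge_arc(params, span, t, ztop) - params.body_length
    return float(brentq(f, 1e-9, params.body_length, xtol=1e-12))


# ---------------------------------------------------------------------------
# shape factories


def cylinder_pig(
    radius: float = 0.3,
    body_length: float = 1.2,
    leg_stub_height: float = 0.25,
    section_exponent: float = 2.0,
) -> PigShapeParams:
    """Constant circular cross-section: the geometry oracle shape.

    Its abdominal circumference is exactly ``2πr`` and its dorsal ridge is
    straight, so every measured quantity has a closed form.
    """
    r = float(radius)

    def profile(t):
        t = np.asarray(t, dtype=float)
        return np.full_like(t, r), np.full_like(t, r)

    return PigShapeParams(
        body_length=body_length,
        cross_section_profile=profile,
        withers_height=leg_stub_height + 2 * r,
        abdominal_max_half_width=r,
        leg_stub_height=leg_stub_height,
        dorsal_curvature=0.0,
        section_exponent=section_exponent,
    )


def _gauss(t, mu, sigma):
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def standard_pig(
    body_length: float = 1.2,
    withers_height: float = 0.63,
    abdominal_max_half_width: float = 0.19,
    leg_stub_height: float = 0.22,
    dorsal_curvature: float = 0.02,
    section_exponent: float = 2.4,
) -> PigShapeParams:
    """Realistic default pig: head and withers bumps, neck dip, abdominal
    bulge at t = 0.55, tapered snout/tail.

    Defaults approximate a finishing Duroc-line pig (height ≈ 63 cm,
    length ≈ 1.2 m, abdominal circumference ≈ 1.15 m).  The half-height
    scale is solved so the withers local maximum sits exactly at
    ``withers_height``; the head bump overtops it, which is what the
    anterior-end detector relies on.
    """
    a_max = float(abdominal_max_half_width)

    def taper(t):
        return np.sqrt(
            np.clip(t / 0.06, 0.0, 1.0) * np.clip((1.0 - t) / 0.06, 0.0, 1.0)
        )

    def hshape(t):
        return (
            (1.0 - 0.08 * t)
            + 0.22 * _gauss(t, 0.07, 0.045)
            - 0.10 * _gauss(t, 0.20, 0.05)
            + 0.12 * _gauss(t, 0.33, 0.08)
        )

    def wshape(t):
        return 0.55 + 0.45 * np.exp(-(((t - 0.55) / 0.28) ** 2))

    w_peak = wshape(np.array(0.55))

    # solve the half-height scale so the withers peak hits withers_height
    arch = lambda t: dorsal_curvature * np.sin(np.pi * t)
    t_w = 0.33
    b0 = (withers_height - leg_stub_height - arch(t_w)) / (2.0 * hshape(np.array(t_w)))
    grid = np.linspace(0.25, 0.45, 2001)
    for _ in range(4):
        ztop = leg_stub_height + 2.0 * b0 * hshape(grid) + arch(grid)
        t_w = float(grid[np.argmax(ztop)])
        b0 = (withers_height - leg_stub_height - arch(t_w)) / (2.0 * hshape(np.array(t_w)))

    def profile(t):
        # width tapers to a rounded snout/tail; the dorsal ridge itself
        # stays gentle so the ridge arc is the back, not the end caps
        t = np.asarray(t, dtype=float)
        return a_max * wshape(t) / w_peak * taper(t), b0 * hshape(t)

    return PigShapeParams(
        body_length=body_length,
        cross_section_profile=profile,
        withers_height=withers_height,
        abdominal_max_half_width=a_max,
        leg_stub_height=leg_stub_height,
        dorsal_curvature=dorsal_curvature,
        section_exponent=section_exponent,
    )


# ---------------------------------------------------------------------------
# sampling


def _superellipse_boundary(phi: np.ndarray, a, b, p: float):
    """Boundary point of |y/a|^p + |z/b|^p = 1 at parameter angle phi."""
    c, s = np.cos(phi), np.sin(phi)
    y = a * np.sign(c) * np.abs(c) ** (2.0 / p)
    z = b * np.sign(s) * np.abs(s) ** (2.0 / p)
    return y, z


def superellipse_perimeter(a: float, b: float, p: float, n: int = 400_001) -> float:
    """Perimeter by dense polygonal (chord-sum) integration."""
    phi = np.linspace(0.0, 2.0 * np.pi, n)
    y, z = _superellipse_boundary(phi, a, b, p)
    return float(np.sum(np.hypot(np.diff(y), np.diff(z))))


def generate_pig_cloud(
    params: PigShapeParams,
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, MorphometryResult]:
    """Sample ``n`` points on the pig surface plus leg stubs.

    Returns the cloud and the analytic ground-truth measurements, which are
    computed from the shape parameters by dense numerical integration and
    are independent of the sampling.
    """
    if n < 100:
        raise InvalidParameterError(f"n must be >= 100, got {n}")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    span = solve_axial_span(params)

    n_leg = 0
    if params.leg_stub_height > 0:
        n_leg = 4 * max(int(0.015 * n), 5)
        n_leg = min(n_leg, n // 4)
    n_trunk = n - n_leg

    t = rng.uniform(0.0, 1.0, n_trunk)
    phi = rng.uniform(0.0, 2.0 * np.pi, n_trunk)
    hw, hh = params.profile(t)
    by, bz = _superellipse_boundary(phi, hw, hh, params.section_exponent)
    zc = params.leg_stub_height + hh + params.arch(t)
    trunk = np.column_stack([span * t, by, zc + bz])

    parts = [trunk]
    if n_leg:
        per_leg = n_leg // 4
        for t_l in params.leg_positions:
            hw_l, _ = params.profile(np.array(t_l))
            for side in (-1.0, 1.0):
                m = per_leg
                ang = rng.uniform(0.0, 2.0 * np.pi, m)
                zz = rng.uniform(0.0, params.leg_stub_height + 0.02, m)
                parts.append(
                    np.column_stack(
                        [
                            span * t_l + params.leg_radius * np.cos(ang),
                            side * 0.55 * float(hw_l) + params.leg_radius * np.sin(ang),
                            zz,
                        ]
                    )
                )
        extra = n_leg - 4 * per_leg
        if extra:
            parts.append(np.repeat(parts[-1][-1:], extra, axis=0))
    points = np.vstack(parts)
    if noise_sd > 0:
        points = points + rng.normal(0.0, noise_sd, points.shape)
    return points, ground_truth_morphometry(params)


# ---------------------------------------------------------------------------
# ground truth


def ground_truth_morphometry(params: PigShapeParams) -> MorphometryResult:
    """Ground-truth measurements by dense numerical integration.

    * length — chord sum along the dorsal ridge (equals ``body_length`` by
      construction of the axial span);
    * height — the withers (second local maximum from the anterior end) of
      the analytic dorsal profile, or the profile maximum when the shape
      has fewer than two maxima (e.g. the cylinder oracle);
    * width — twice the maximum half-width;
    * circumference — polygonal perimeter of the cross-section at the
      position of maximum half-width.
    """
    span = solve_axial_span(params)
    t = np.linspace(0.0, 1.0, _GRID)
    ztop = params.top_height(t)
    length = _ridge_arc(params, span, t, ztop)

    peaks, _ = find_peaks(ztop, prominence=1e-4)
    if len(peaks) >= 2:
        if ztop[peaks[-1]] > ztop[peaks[0]]:
            peaks = peaks[::-1]
        height = float(ztop[peaks[1]])
    else:
        height = float(ztop.max())

    hw, hh = params.profile(t)
    i_star = int(np.argmax(hw))
    width = 2.0 * float(hw[i_star])
    circumference = superellipse_perimeter(
        float(hw[i_star]), float(hh[i_star]), params.section_exponent
    )
    return MorphometryResult(
        length=length,
        height=height,
        width=width,
        abdominal_circumference=circumference,
        slice_position=float(span * t[i_star]),
    )
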