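"""Low-cost approximations to the series-unidirectional resistance.

Four estimators avoid the per-section Poisson solve:

* Method I scales a single reference resistance by (A_ref/A)², assuming the
  section shape is uniform along the duct.
* Method II multiplies the Hagen-Poiseuille circular resistance by a shape
  factor γ built from boundary-point distances to an optimal interior
  center (the point minimizing γ, near the velocity maximum).
* Method III evaluates the elliptical-duct lubrication result using the
  matched-ellipse aspect ratio β.
* Method IV uses the polar second moment of area, R = 16π²µ I_p / A⁴.

Methods III and IV are exact for true ellipses; all four reduce to
Hagen-Poiseuille on circles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from shapely.geometry import Point
from shapely.geometry import Polygon as _ShapelyPolygon

from ._fem import resample_boundary
from .geometry import CrossSection, CrossSectionMetrics, polygon_metrics


@dataclass(frozen=True)
class ShapeFactorResult:
    """Shape factor γ of Method II with its minimizing center."""

    gamma: float
    center: tuple[float, float]
    d: np.ndarray
    N: int


def method_I(metrics_i: CrossSectionMetrics, R_ref: float, A_ref: float) -> float:
    """R_I = R_ref (A_ref / A_i)²: pure area scaling from a reference section."""
    if metrics_i.A <= 0 or A_ref <= 0:
        raise ValueError("areas must be positive")
    return R_ref * (A_ref / metrics_i.A) ** 2


def shape_factor(
    section: CrossSection, N: int = 100, center=None
) -> ShapeFactorResult:
    """γ = (1/N) Σ (r_eq/d_j)⁴ over N equally spaced boundary points.

    If ``center`` is None it is found by derivative-free minimization of γ
    over interior points, started at the centroid (or the polygon's
    representative point when the centroid falls outside, as it can for
    crescent-shaped sections) and restarted from a coarse interior grid if
    the optimizer strays outside the polygon.
    """
    if N < 16:
        raise ValueError("need N >= 16 boundary points")
    m = polygon_metrics(section)
    pts = resample_boundary(section.vertices, N)
    poly = _ShapelyPolygon(section.vertices)

    def gamma_at(c: np.ndarray) -> float:
        if not poly.contains(Point(c)):
            return np.inf
        d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
        if np.any(d <= 0):
            return np.inf
        return float(np.mean((m.r_eq / d) ** 4))

    if center is not None:
        c = np.asarray(center, float)
        g = gamma_at(c)
        if not np.isfinite(g):
            raise ValueError("prescribed center lies outside the polygon")
        d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
        return ShapeFactorResult(gamma=g, center=(c[0], c[1]), d=d, N=N)

    # simplex polish from the centroid plus the best point of a coarse
    # interior scan: gamma is multimodal for bi-lobed and dumbbell shapes,
    # and a symmetric centroid start can sit on a saddle
    starts = []
    if poly.contains(Point(m.centroid)):
        starts.append(np.asarray(m.centroid))
    else:
        rp = poly.representative_point()
        starts.append(np.array([rp.x, rp.y]))
    minx, miny, maxx, maxy = poly.bounds
    gx, gy = np.meshgrid(np.linspace(minx, maxx, 12), np.linspace(miny, maxy, 12))
    cand = np.column_stack([gx.ravel(), gy.ravel()])
    vals = np.array([gamma_at(c) for c in cand])
    if np.any(np.isfinite(vals)):
        starts.append(cand[int(np.argmin(vals))])

    best_c, best_g = None, np.inf
    for s in starts:
        res = minimize(
            gamma_at, s, method="Nelder-Mead",
            options={"xatol": 1e-4 * m.r_eq, "fatol": 1e-10, "maxiter": 400},
        )
        if res.fun < best_g and poly.contains(Point(res.x)):
            best_g, best_c = float(res.fun), res.x
    if best_c is None:
        raise RuntimeError("gamma minimization failed to stay inside the polygon")

    d = np.hypot(pts[:, 0] - best_c[0], pts[:, 1] - best_c[1])
    return ShapeFactorResult(
        gamma=best_g, center=(float(best_c[0]), float(best_c[1])), d=d, N=N
    )


def method_II(
    section: CrossSection, mu: float = 6.9e-4, N: int = 100, center=None
) -> tuple[float, ShapeFactorResult]:
    """R_II = 8µγ/(π r_eq⁴): shape-factor-scaled Hagen-Poiseuille."""
    m = polygon_metrics(section)
    sf = shape_factor(section, N=N, center=center)
    return 8.0 * mu * sf.gamma / (np.pi * m.r_eq**4), sf


def method_III(metrics: CrossSectionMetrics, mu: float = 6.9e-4) -> float:
    """R_III = 4µ(β²+1)/(π r_eq⁴ β): elliptical lubrication result with the
    matched-ellipse aspect ratio."""
    if metrics.beta < 1:
        raise ValueError("beta must be >= 1")
    return 4.0 * mu * (metrics.beta**2 + 1.0) / (np.pi * metrics.r_eq**4 * metrics.beta)


def method_IV(
    section_or_metrics: CrossSection | CrossSectionMetrics, mu: float = 6.9e-4
) -> float:
    """R_IV = 16π²µ I_p / A⁴ using the exact polygon polar moment."""
    m = (
        section_or_metrics
        if isinstance(section_or_metrics, CrossSectionMetrics)
        else polygon_metrics(section_or_metrics)
    )
    return 16.0 * np.pi**2 * mu * m.I_p / m.A**4
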