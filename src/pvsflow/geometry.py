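"""Cross-section and duct geometry.

A duct (e.g. a pial perivascular space) is described by an ordered stack of
planar cross sections along a centerline.  Each cross section is a simple
polygon in its own local frame; the stack carries the axial station ``z`` of
every section.  This module computes per-section shape metrics (area,
perimeter, second moments, matched-ellipse aspect ratio), builds the axial
area profile A(z) with its first and second derivatives, constructs the
area-matched circularized duct, and provides centerline-curvature
diagnostics (Dean number).

Units are micrometres throughout: areas in µm², moments in µm⁴.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import ellipe
from shapely.geometry import Polygon as _ShapelyPolygon


class InvalidGeometryError(ValueError):
    """Raised for degenerate or self-intersecting cross sections."""


def _as_vertex_array(vertices) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise InvalidGeometryError(
            f"polygon needs >= 3 planar vertices, got shape {v.shape}"
        )
    # drop an explicitly closed last vertex
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    if v.shape[0] < 3:
        raise InvalidGeometryError("polygon needs >= 3 distinct vertices")
    return v


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class CrossSection:
    """A planar cross section at axial station ``z``.

    ``vertices`` are counter-clockwise boundary points (µm) in the section's
    local frame; clockwise input is re-oriented on construction.
    ``axial_vector`` is the unit centerline tangent and ``centerline_point``
    the 3D location of the section's center, both used only for bookkeeping
    and curvature diagnostics -- the resistance estimators are frame
    invariant.
    """

    z: float
    vertices: np.ndarray
    axial_vector: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    centerline_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        v = _as_vertex_array(self.vertices)
        sa = _signed_area(v)
        if sa < 0.0:
            v = v[::-1]
            sa = -sa
        if sa <= 0.0:
            raise InvalidGeometryError(f"degenerate polygon at z={self.z}: area <= 0")
        if not _ShapelyPolygon(v).is_valid:
            raise InvalidGeometryError(f"self-intersecting polygon at z={self.z}")
        self.vertices = v
        self.axial_vector = np.asarray(self.axial_vector, dtype=float)
        n = np.linalg.norm(self.axial_vector)
        if n > 0:
            self.axial_vector = self.axial_vector / n
        self.centerline_point = np.asarray(self.centerline_point, dtype=float)

    @property
    def polygon(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


@dataclass(frozen=True)
class CrossSectionMetrics:
    """Shape metrics of one cross section.

    ``I_xx = ∫(y-y0)² dA`` and ``I_yy = ∫(x-x0)² dA`` are central second
    moments, ``I_p = I_xx + I_yy`` the polar moment, and ``beta >= 1`` the
    aspect ratio of the ellipse with the same central second-moment tensor.
    """

    A: float
    P: float
    D_h: float
    r_eq: float
    centroid: tuple[float, float]
    I_xx: float
    I_yy: float
    I_xy: float
    I_p: float
    beta: float

    @classmethod
    def from_ellipse(cls, b: float, c: float) -> "CrossSectionMetrics":
        """Exact analytic metrics of an ellipse with semi-axes b >= c > 0."""
        if not (b >= c > 0):
            raise InvalidGeometryError("ellipse requires b >= c > 0")
        A = np.pi * b * c
        # exact perimeter via the complete elliptic integral of the 2nd kind
        P = 4.0 * b * float(ellipe(1.0 - (c / b) ** 2))
        I_yy = np.pi * b**3 * c / 4.0  # ∫x² dA
        I_xx = np.pi * b * c**3 / 4.0  # ∫y² dA
        return cls(
            A=A, P=P, D_h=4.0 * A / P, r_eq=float(np.sqrt(A / np.pi)),
            centroid=(0.0, 0.0), I_xx=I_xx, I_yy=I_yy, I_xy=0.0,
            I_p=I_xx + I_yy, beta=b / c,
        )


def polygon_metrics(section: CrossSection) -> CrossSectionMetrics:
    """Exact polygon metrics: shoelace area, centroid, central second moments.

    The matched-ellipse aspect ratio is β = sqrt(λ₁/λ₂) with λ₁ >= λ₂ the
    eigenvalues of the central second-moment tensor; for a discretized
    ellipse with semi-axes b >= c this recovers b/c.
    """
    v = section.vertices
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    A = 0.5 * float(np.sum(cross))
    if A <= 0.0:
        raise InvalidGeometryError("polygon area <= 0")
    cx = float(np.sum((x + x1) * cross)) / (6.0 * A)
    cy = float(np.sum((y + y1) * cross)) / (6.0 * A)
    # second moments about the origin (standard shoelace moment formulas)
    iyy0 = float(np.sum((x**2 + x * x1 + x1**2) * cross)) / 12.0  # ∫x²
    ixx0 = float(np.sum((y**2 + y * y1 + y1**2) * cross)) / 12.0  # ∫y²
    ixy0 = float(np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross)) / 24.0
    # shift to centroid
    I_yy = iyy0 - A * cx**2
    I_xx = ixx0 - A * cy**2
    I_xy = ixy0 - A * cx * cy
    # eigenvalues of [[I_yy, I_xy], [I_xy, I_xx]]
    tr = I_xx + I_yy
    det = I_xx * I_yy - I_xy**2
    disc = max(tr**2 / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + np.sqrt(disc)
    lam2 = tr / 2.0 - np.sqrt(disc)
    if lam2 <= 0.0:
        raise InvalidGeometryError("degenerate second-moment tensor")
    beta = float(np.sqrt(lam1 / lam2))
    P = float(np.sum(np.hypot(x1 - x, y1 - y)))
    return CrossSectionMetrics(
        A=A, P=P, D_h=4.0 * A / P, r_eq=float(np.sqrt(A / np.pi)),
        centroid=(cx, cy), I_xx=I_xx, I_yy=I_yy, I_xy=I_xy,
        I_p=I_xx + I_yy, beta=beta,
    )


@dataclass(frozen=True)
class FluidSpec:
    """Newtonian fluid and imposed steady flow rate.

    ``mu`` in Pa·s (default: water at 37 °C), ``Q`` in µm³/s (default: a
    typical pial perivascular CSF flow rate).  In Stokes flow the resistance
    per unit length is independent of Q; Q only scales the oracle's fields.
    """

    mu: float = 6.9e-4
    Q: float = 2.19e4

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.Q <= 0:
            raise ValueError("mu and Q must be positive")


@dataclass
class DuctGeometry:
    """An ordered stack of cross sections plus its axial area profile.

    ``area_profile``, ``dA_dz`` and ``d2A_dz2`` are sampled at the original
    stations ``z``; ``grid_z``/``grid_A`` (with derivatives) live on the
    uniform resampled grid on which the finite differences were taken.
    """

    sections: list[CrossSection]
    spacing: float
    z: np.ndarray
    area_profile: np.ndarray
    dA_dz: np.ndarray
    d2A_dz2: np.ndarray
    grid_z: np.ndarray
    grid_A: np.ndarray
    grid_dA: np.ndarray
    grid_d2A: np.ndarray
    smooth_window: int | None = None
    circular: bool = False

    def __len__(self) -> int:
        return len(self.sections)

    @property
    def length(self) -> float:
        return float(self.z[-1] - self.z[0])

    def section_metrics(self) -> list[CrossSectionMetrics]:
        return [polygon_metrics(s) for s in self.sections]

    def radius_profile(self) -> np.ndarray:
        """Equivalent radius sqrt(A/π) at each station."""
        return np.sqrt(self.area_profile / np.pi)


def build_duct(
    sections: list[CrossSection],
    resample_dz: float = 0.7,
    smooth_window: int | None = None,
    circular: bool = False,
) -> DuctGeometry:
    """Assemble a :class:`DuctGeometry` from ordered cross sections.

    A(z) is evaluated at the stations, interpolated with a cubic spline onto
    a uniform grid of spacing ``resample_dz``, optionally boxcar-smoothed
    (``smooth_window`` samples, odd), and differentiated by second-order
    central differences (one-sided at the ends).  Central differencing on a
    uniform grid is exact for quadratic A(z).
    """
    if len(sections) < 5:
        raise InvalidGeometryError("need >= 5 cross sections")
    z = np.array([s.z for s in sections], dtype=float)
    if not np.all(np.diff(z) > 0):
        bad = int(np.argmax(np.diff(z) <= 0)) + 1
        raise InvalidGeometryError(f"z stations must strictly increase (section {bad})")
    A = np.array([polygon_metrics(s).A for s in sections])

    n_grid = max(int(round((z[-1] - z[0]) / resample_dz)) + 1, 5)
    gz = np.linspace(z[0], z[-1], n_grid)
    dz = gz[1] - gz[0]
    gA = CubicSpline(z, A)(gz)
    if smooth_window is not None and smooth_window > 1:
        w = int(smooth_window) | 1  # force odd
        pad = w // 2
        padded = np.pad(gA, pad, mode="edge")
        gA = np.convolve(padded, np.ones(w) / w, mode="valid")
    gdA = np.gradient(gA, dz, edge_order=2)
    gd2A = np.gradient(gdA, dz, edge_order=2)

    dA = np.interp(z, gz, gdA)
    d2A = np.interp(z, gz, gd2A)
    return DuctGeometry(
        sections=list(sections), spacing=resample_dz, z=z, area_profile=A,
        dA_dz=dA, d2A_dz2=d2A, grid_z=gz, grid_A=gA, grid_dA=gdA,
        grid_d2A=gd2A, smooth_window=smooth_window, circular=circular,
    )


def circle_polygon(r: float, n_vertices: int = 128, center=(0.0, 0.0)) -> np.ndarray:
    """Counter-clockwise regular n-gon inscribed in a circle of radius r."""
    th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def circularize(duct: DuctGeometry, n_vertices: int = 128) -> DuctGeometry:
    """Replace each section by a circle of equal area on a straight axis.

    The circularized duct preserves the axial area profile A(z) while
    removing all shape information, isolating area effects from shape
    effects on the resistance.
    """
    new_sections = []
    for s, A in zip(duct.sections, duct.area_profile):
        r = float(np.sqrt(A / np.pi))
        new_sections.append(
            CrossSection(
                z=s.z,
                vertices=circle_polygon(r, n_vertices),
                axial_vector=np.array([0.0, 0.0, 1.0]),
                centerline_point=np.array([0.0, 0.0, s.z]),
            )
        )
    return build_duct(
        new_sections, resample_dz=duct.spacing,
        smooth_window=duct.smooth_window, circular=True,
    )


def dean_number(Re: float, r_e: float, r_c: float) -> float:
    """Dean number De = Re·sqrt(r_e/r_c).

    Measures the strength of centerline-curvature secondary flows; for pial
    perivascular spaces (Re ~ 1e-3, r_e ~ 6 µm, r_c >~ 100 µm) De ~ 2.5e-4,
    so curvature effects on resistance are negligible.
    """
    if r_e < 0 or r_c <= 0:
        raise ValueError("r_e must be >= 0 and r_c > 0")
    if np.isinf(r_c):
        return 0.0
    return float(Re * np.sqrt(r_e / r_c))


def centerline_curvature_radius(points: np.ndarray) -> np.ndarray:
    """Per-station radius of curvature from three consecutive centerline points.

    Returns the circumradius of each interior point's triangle of neighbours;
    ``inf`` for (near-)collinear triples, and at the two end stations.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    r_c = np.full(n, np.inf)
    for i in range(1, n - 1):
        a, b, c = pts[i - 1], pts[i], pts[i + 1]
        la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c),
                      np.linalg.norm(a - b))
        cr = np.linalg.norm(np.cross(b - a, c - a))
        if cr > 1e-12 * lb * lc:
            r_c[i] = la * lb * lc / (2.0 * cr)
    return r_c
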