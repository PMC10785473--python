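"""Parametric duct generators.

Three families of synthetic ducts exercise every estimator without any
imaging data:

* a circular duct with sinusoidally varying radius (the classic
  unidirectional-flow stress test),
* nonuniform elliptical ducts b(z), c(z) with analytic derivative
  callbacks for cross-checking the lubrication formulas,
* bi-lobed ducts emulating the statistics of murine pial perivascular
  lobes: a crescent-shaped section (outer ellipse minus the vessel disk,
  one lobe kept), mean area near 100 µm², matched-ellipse aspect ratio
  between about 1.1 and 2, smooth random axial variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from shapely.geometry import Point
from shapely.geometry import Polygon as _ShapelyPolygon

from ._fem import resample_boundary
from .geometry import CrossSection, DuctGeometry, build_duct, circle_polygon


@dataclass(frozen=True)
class SinusoidSpec:
    """Circular duct with r(z) = r0 + amp·sin(2πz/wavelength), in µm."""

    r0: float = 50.0
    amp: float = 1.5
    wavelength: float = 50.0
    length: float = 100.0
    dz: float = 0.7

    def __post_init__(self) -> None:
        if not (0 <= self.amp < self.r0):
            raise ValueError("need 0 <= amp < r0")
        if self.dz <= 0 or self.length <= 0 or self.wavelength <= 0:
            raise ValueError("dz, length, wavelength must be positive")

    def radius(self, z) -> np.ndarray:
        return self.r0 + self.amp * np.sin(2.0 * np.pi * np.asarray(z) / self.wavelength)


def make_sinusoidal_duct(
    spec: SinusoidSpec = SinusoidSpec(), n_vertices: int = 128
) -> DuctGeometry:
    """Build the sinusoidal-radius circular duct described by ``spec``."""
    z = np.arange(0.0, spec.length + 0.5 * spec.dz, spec.dz)
    sections = [
        CrossSection(
            z=float(zi),
            vertices=circle_polygon(float(spec.radius(zi)), n_vertices),
            centerline_point=np.array([0.0, 0.0, zi]),
        )
        for zi in z
    ]
    return build_duct(sections, resample_dz=spec.dz, circular=True)


def make_elliptical_duct(
    b_of_z: Callable[[float], float] | float,
    c_of_z: Callable[[float], float] | float,
    length: float,
    dz: float = 0.7,
    n_vertices: int = 128,
    derivatives: tuple[Callable, Callable, Callable, Callable] | None = None,
) -> DuctGeometry:
    """Elliptical duct with semi-axes b(z), c(z).

    ``derivatives``, if given, are callables (b', c', b'', c''); otherwise
    they are built by central finite differences of the axis callables
    (adequate for plotting and rough checks, not for tight identities).
    The callbacks are attached to the duct as ``duct.ellipse_callbacks``.
    """
    bf = b_of_z if callable(b_of_z) else (lambda z, v=float(b_of_z): v)
    cf = c_of_z if callable(c_of_z) else (lambda z, v=float(c_of_z): v)
    z = np.arange(0.0, length + 0.5 * dz, dz)
    sections = []
    for zi in z:
        b, c = float(bf(zi)), float(cf(zi))
        if b <= 0 or c <= 0:
            raise ValueError(f"nonpositive semi-axis at z={zi}")
        th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        verts = np.column_stack([b * np.cos(th), c * np.sin(th)])
        sections.append(
            CrossSection(z=float(zi), vertices=verts,
                         centerline_point=np.array([0.0, 0.0, zi]))
        )
    duct = build_duct(sections, resample_dz=dz)
    if derivatives is None:
        h = 1e-4 * max(length, 1.0)

        def _d1(f):
            return lambda zz: (f(zz + h) - f(zz - h)) / (2.0 * h)

        def _d2(f):
            return lambda zz: (f(zz + h) - 2.0 * f(zz) + f(zz - h)) / h**2

        derivatives = (_d1(bf), _d1(cf), _d2(bf), _d2(cf))
    duct.ellipse_callbacks = {
        "b": bf, "c": cf, "db": derivatives[0], "dc": derivatives[1],
        "d2b": derivatives[2], "d2c": derivatives[3],
    }
    return duct


def make_perturbed_ellipse_section(
    b: float = 6.0,
    c: float = 5.0,
    harmonic_amp: float = 0.025,
    seed: int = 0,
    z: float = 0.0,
    n_vertices: int = 200,
) -> CrossSection:
    """A bumpy near-elliptical section: ellipse (b, c) with smooth random
    radial harmonics (wavenumbers 2-5) of relative amplitude ``harmonic_amp``.

    Emulates moderately irregular, not-too-oblong duct cross sections (the
    regime where shape-factor resistance estimates are reliable).
    """
    rng = np.random.default_rng(seed)
    th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    rho = np.ones_like(th)
    for k in range(2, 6):
        rho += harmonic_amp * rng.standard_normal() * np.cos(
            k * th + rng.uniform(0, 2 * np.pi)
        )
    return CrossSection(
        z=z, vertices=np.column_stack([b * rho * np.cos(th), c * rho * np.sin(th)])
    )


@dataclass(frozen=True)
class BilobeSpec:
    """Crescent-lobe duct emulating a pial perivascular space.

    The section is the x > 0 lobe of (outer ellipse) minus (vessel disk).
    Ellipse semi-axes are ``lobe_scale``·vessel_radius along x and
    ``eccentricity``·vessel_radius along y; defaults give a mean area near
    100 µm² with matched-ellipse aspect ratios in the observed 1.1-2 band.
    ``axial_modulation = (amplitude, wavelength)`` modulates the outer
    ellipse axes sinusoidally; a seeded low-frequency random component is
    superposed so repeated sections differ smoothly.
    """

    vessel_radius: float = 12.0
    lobe_scale: float = 1.7
    eccentricity: float = 0.8
    axial_modulation: tuple[float, float] = (0.06, 50.0)
    noise: float = 0.02
    length: float = 70.0
    dz: float = 0.7
    seed: int = 0
    n_boundary: int = 100

    def __post_init__(self) -> None:
        if self.vessel_radius <= 0 or self.lobe_scale <= 1.0:
            raise ValueError("vessel_radius > 0 and lobe_scale > 1 required")
        if not (0 < self.eccentricity < 1):
            raise ValueError("eccentricity must be in (0, 1) to split the lobes")


def _lobe_polygon(r_v: float, ax: float, ay: float, n: int) -> np.ndarray:
    """One crescent lobe: (ellipse minus vessel disk) restricted to x > 0."""
    th = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    ellipse = _ShapelyPolygon(np.column_stack([ax * np.cos(th), ay * np.sin(th)]))
    vessel = Point(0.0, 0.0).buffer(r_v, quad_segs=64)
    diff = ellipse.difference(vessel)
    lobes = list(diff.geoms) if diff.geom_type == "MultiPolygon" else [diff]
    lobe = max(
        (g for g in lobes if g.centroid.x > 0),
        key=lambda g: g.area,
        default=None,
    )
    if lobe is None or lobe.is_empty:
        raise ValueError("lobe construction produced no x > 0 component")
    verts = np.asarray(lobe.exterior.coords)[:-1]
    return resample_boundary(verts, n)


def make_bilobed_duct(spec: BilobeSpec = BilobeSpec()) -> DuctGeometry:
    """Generate a bi-lobe-style duct; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    amp, wav = spec.axial_modulation
    z = np.arange(0.0, spec.length + 0.5 * spec.dz, spec.dz)
    L = max(spec.length, 1.0)
    # smooth random axial modes (k = 1..3) for each ellipse axis
    kx = np.arange(1, 4)
    ax_amp = spec.noise * rng.standard_normal(3)
    ax_ph = rng.uniform(0, 2 * np.pi, 3)
    ay_amp = spec.noise * rng.standard_normal(3)
    ay_ph = rng.uniform(0, 2 * np.pi, 3)
    phi0 = rng.uniform(0, 2 * np.pi)

    ax0 = spec.lobe_scale * spec.vessel_radius
    ay0 = spec.eccentricity * spec.vessel_radius

    sections = []
    for zi in z:
        mod = amp * np.sin(2 * np.pi * zi / wav + phi0) if amp else 0.0
        fx = 1.0 + mod + float(np.sum(ax_amp * np.sin(2 * np.pi * kx * zi / L + ax_ph)))
        fy = 1.0 + mod + float(np.sum(ay_amp * np.sin(2 * np.pi * kx * zi / L + ay_ph)))
        verts = None
        for attempt in range(10):
            shrink = 0.5**attempt
            try:
                cand = _lobe_polygon(
                    spec.vessel_radius,
                    ax0 * (1.0 + (fx - 1.0) * shrink),
                    ay0 * (1.0 + (fy - 1.0) * shrink),
                    spec.n_boundary,
                )
            except ValueError:
                continue
            if _ShapelyPolygon(cand).is_valid:
                verts = cand
                break
        if verts is None:
            raise RuntimeError(f"could not build a simple lobe polygon at z={zi}")
        sections.append(
            CrossSection(z=float(zi), vertices=verts,
                         centerline_point=np.array([0.0, 0.0, zi]))
        )
    return build_duct(sections, resample_dz=spec.dz)
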