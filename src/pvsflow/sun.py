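"""Series-unidirectional resistance estimators.

A nonuniform duct is modelled as a chain of uniform ducts, one per cross
section, each carrying purely axial Poiseuille-type flow.  The hydraulic
resistance per unit length R = -(dp/dz)/Q of each uniform duct is obtained
either numerically (SUN: a 2D Poisson solve of the axial momentum balance
µ ∇²w = dp/dz with no-slip walls) or analytically for circles
(SUA: Hagen-Poiseuille, 8µ/(π r⁴)).  Because the flow is Stokes, R is
independent of the flow rate and the solve uses a unit pressure gradient.

Resistances are in Pa·s/µm⁴ when µ is in Pa·s and lengths in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fem
from .geometry import CrossSection, DuctGeometry, FluidSpec, polygon_metrics

#: mesh edge length as a fraction of the equivalent radius; calibrated so
#: the circle benchmark error is well below the 0.5% criterion
DEFAULT_MESH_FRACTION = 1.0 / 24.0


@dataclass
class ResistanceProfile:
    """Per-station hydraulic resistance along a duct.

    ``R_local`` holds R at each station ``z`` (Pa·s/µm⁴), tagged with the
    estimator ``method``.  ``valid`` masks stations included in the average
    (the axisymmetric oracle excludes exit-affected tail stations).
    """

    z: np.ndarray
    R_local: np.ndarray
    method: str
    A_um2: np.ndarray | None = None
    d2A_dz2: np.ndarray | None = None
    valid: np.ndarray | None = field(default=None)

    @property
    def R_avg(self) -> float:
        mask = self.valid if self.valid is not None else np.ones(len(self.z), bool)
        return float(np.mean(self.R_local[mask]))

    @property
    def R_total(self) -> float:
        """Total resistance: trapezoidal integral of R over z (Pa·s/µm³)."""
        return float(np.trapezoid(self.R_local, self.z))

    def with_values(self, R_new: np.ndarray, method: str) -> "ResistanceProfile":
        return ResistanceProfile(
            z=self.z.copy(), R_local=np.asarray(R_new, float), method=method,
            A_um2=self.A_um2, d2A_dz2=self.d2A_dz2, valid=self.valid,
        )


def sun_resistance(
    section: CrossSection, mu: float = 6.9e-4, mesh_size: float | None = None,
) -> float:
    """Resistance per unit length from a P1 FEM Poisson solve (SUN).

    Solves µ ∇²w = dp/dz with w = 0 on the polygon boundary for a unit
    pressure gradient and returns R = |dp/dz| / ∫ w dA.  ``mesh_size`` is
    the target element edge length (µm); the default scales with the
    section's equivalent radius and meets the 0.5% circle benchmark.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    m = polygon_metrics(section)
    h = mesh_size if mesh_size is not None else DEFAULT_MESH_FRACTION * m.r_eq
    try:
        pts, tris, n_b = _fem.triangulate_polygon(section.vertices, h)
        _, Q = _fem.poisson_flow(pts, tris, n_b, mu)
    except _fem.MeshingError as exc:
        raise _fem.MeshingError(
            f"meshing failed for section at z={section.z} "
            f"(A={m.A:.3g} µm², {len(section.vertices)} vertices): {exc}"
        ) from exc
    return 1.0 / Q


def sua_circle(r_eq: float, mu: float = 6.9e-4) -> float:
    """Hagen-Poiseuille resistance per unit length of a circle: 8µ/(π r⁴)."""
    if r_eq <= 0:
        raise ValueError("r_eq must be positive")
    return 8.0 * mu / (np.pi * r_eq**4)


def circle_benchmark_error(
    r: float = 5.0, mu: float = 1.0, mesh_size: float | None = None,
    n_vertices: int = 256,
) -> float:
    """Percent error of SUN vs Hagen-Poiseuille on a circle (mesh calibration)."""
    from .geometry import circle_polygon

    sec = CrossSection(z=0.0, vertices=circle_polygon(r, n_vertices))
    R = sun_resistance(sec, mu=mu, mesh_size=mesh_size)
    R_exact = sua_circle(r, mu)
    return 100.0 * abs(R - R_exact) / R_exact


def series_profile(
    duct: DuctGeometry,
    fluid: FluidSpec = FluidSpec(),
    method: str = "SUN",
    mesh_size: float | None = None,
    N_boundary: int = 100,
    reference: str | int = "max",
) -> ResistanceProfile:
    """Apply a per-section estimator at every station of a duct.

    ``method`` is one of SUN, SUA, I, II, III, IV.  SUA is only valid for
    circular ducts.  Method I uses the SUN resistance of the reference
    section (``reference``: "max" / "min" area, or a station index).
    """
    from . import quick

    method = method.upper()
    metrics = duct.section_metrics()
    A = np.array([m.A for m in metrics])
    mu = fluid.mu

    if method == "SUN":
        R = np.array(
            [sun_resistance(s, mu, mesh_size) for s in duct.sections]
        )
    elif method == "SUA":
        if not duct.circular:
            raise ValueError(
                "SUA is only valid for circular ducts; use SUN (or circularize first)"
            )
        R = np.array([sua_circle(m.r_eq, mu) for m in metrics])
    elif method == "I":
        if reference == "max":
            i_ref = int(np.argmax(A))
        elif reference == "min":
            i_ref = int(np.argmin(A))
        else:
            i_ref = int(reference)
        R_ref = sun_resistance(duct.sections[i_ref], mu, mesh_size)
        R = np.array(
            [quick.method_I(m, R_ref=R_ref, A_ref=A[i_ref]) for m in metrics]
        )
    elif method == "II":
        R = np.array(
            [quick.method_II(s, mu, N=N_boundary)[0] for s in duct.sections]
        )
    elif method == "III":
        R = np.array([quick.method_III(m, mu) for m in metrics])
    elif method == "IV":
        R = np.array([quick.method_IV(m, mu) for m in metrics])
    else:
        raise ValueError(f"unknown method {method!r}")

    return ResistanceProfile(
        z=duct.z.copy(), R_local=R, method=method, A_um2=A,
        d2A_dz2=duct.d2A_dz2.copy(),
    )
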