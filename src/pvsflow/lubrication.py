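"""Lubrication theory for nonuniform elliptical ducts.

For a duct whose cross section is the ellipse (x/b(z))² + (y/c(z))² = 1,
classical (0th-order) lubrication theory gives the local resistance of the
equivalent uniform duct,

    R0 = 4µ (b² + c²) / (π b³ c³) = 4πµ (β² + 1) / (β A²),

and the 2nd-order extension adds a term R2 that depends on the wall slopes
and curvatures (b', c', b'', c'').  The total resistance per unit length is
R0 + R2 (working in dimensional variables, where the formal aspect-ratio
expansion parameter is absorbed into the axial derivatives).  The
fractional error of the uniform-duct approximation, E ≈ R2/R0, is
dominated by the second derivative of the area:

    E ≈ P(β) · A''  with  P(β) = (β⁴ + 14β² + 1) / (48πβ(β² + 1)),

P(1) = 1/(6π).  Inverting the resulting percent-error line err% = s·A'' + i
yields a multiplicative correction λ(A'') = 100 / (100 + s·A'' + i) that
moves a series-unidirectional resistance toward the full 3D value.  Slope
and intercept pairs fitted against 3D simulations of murine perivascular
geometries are provided alongside the purely analytic circular-duct slope
-100/(6π).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sun import ResistanceProfile


@dataclass(frozen=True)
class EllipseProfile:
    """Local ellipse semi-axes and their axial derivatives at one station."""

    b: float
    c: float
    db_dz: float = 0.0
    dc_dz: float = 0.0
    d2b_dz2: float = 0.0
    d2c_dz2: float = 0.0

    def __post_init__(self) -> None:
        if self.b <= 0 or self.c <= 0:
            raise ValueError("semi-axes must be positive")


def ellipse_R0(p: EllipseProfile, mu: float = 6.9e-4) -> float:
    """0th-order (uniform-duct) resistance: 4µ(b²+c²)/(πb³c³)."""
    return 4.0 * mu * (p.b**2 + p.c**2) / (np.pi * p.b**3 * p.c**3)


def ellipse_R0_area_form(A: float, beta: float, mu: float = 6.9e-4) -> float:
    """Equivalent area/aspect-ratio form: 4πµ(β²+1)/(βA²)."""
    return 4.0 * np.pi * mu * (beta**2 + 1.0) / (beta * A**2)


def ellipse_R2(p: EllipseProfile, mu: float = 6.9e-4) -> float:
    """2nd-order resistance correction for a nonuniform elliptical duct.

    Symmetric under (b, b', b'') <-> (c, c', c''); zero for a uniform duct.
    Negative at bulges (where the uniform-duct estimate is high) and
    positive at constrictions.
    """
    b, c = p.b, p.c
    db, dc = p.db_dz, p.dc_dz
    d2b, d2c = p.d2b_dz2, p.d2c_dz2
    bracket = (
        3.0 * c**4 * db * dc
        + b**3 * c * (2.0 * db**2 - 7.0 * c * d2c + 8.0 * dc**2)
        + b * c**3 * (8.0 * db**2 - c * d2c + 2.0 * dc**2)
        + b**4 * (3.0 * db * dc - c * d2b)
        + b**2 * c**2 * (6.0 * db * dc - 7.0 * c * d2b)
    )
    return -mu / (6.0 * np.pi * b**4 * c**4) * bracket


def fixed_beta_R2(
    A: float, dA_dz: float, d2A_dz2: float, beta: float, mu: float = 6.9e-4
) -> float:
    """2nd-order correction for a self-similar duct (dβ/dz = 0).

    Equivalent to :func:`ellipse_R2` whenever the cross sections scale
    uniformly along the duct, but requires only the area profile.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    s1 = 1.0 + 6.0 * beta**2 + beta**4
    s2 = 1.0 + 14.0 * beta**2 + beta**4
    return -mu / (12.0 * beta**2 * A**2) * (3.0 * dA_dz**2 / A * s1 - d2A_dz2 * s2)


def beta_prefactor(beta) -> np.ndarray | float:
    """P(β) = (β⁴+14β²+1)/(48πβ(β²+1)), the aspect-ratio weight of the
    leading-order error; P(1) = 1/(6π) and P(β) = P(1/β)."""
    beta = np.asarray(beta, dtype=float)
    out = (beta**4 + 14.0 * beta**2 + 1.0) / (
        48.0 * np.pi * beta * (beta**2 + 1.0)
    )
    return float(out) if out.ndim == 0 else out


def beta_prefactor_max_deviation(
    beta_max: float = 7.0, step: float | None = None
) -> float:
    """Max percent deviation of P(β) from P(1) over β ∈ [1, beta_max).

    ``step=None`` scans continuously (dense grid); a finite step (e.g. 0.5)
    evaluates on that grid only.
    """
    if step is None:
        betas = np.linspace(1.0, beta_max, 200001)[:-1]
    else:
        betas = np.arange(1.0, beta_max, step)
    p = beta_prefactor(betas)
    p1 = beta_prefactor(1.0)
    return float(np.max(100.0 * np.abs(p - p1) / p1))


def elt_error(
    A: float, dA_dz: float, d2A_dz2: float, beta: float = 1.0, alpha: float = 1.0
) -> tuple[float, float]:
    """Fractional error of the uniform-duct approximation, E ≈ R2/R0.

    Returns ``(full, leading)``: the full expression containing both the
    A'² and A'' terms, and the leading-order form P(β)·A'' valid for small
    relative area variations.  ``alpha`` is the duct aspect ratio of the
    nondimensional expansion; with dimensional axial derivatives (the
    default bookkeeping throughout this package) leave it at 1.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    s1 = 6.0 * beta**2 + beta**4 + 1.0
    s2 = beta**4 + 14.0 * beta**2 + 1.0
    full = (
        alpha**2
        / (48.0 * np.pi * beta * (beta**2 + 1.0))
        * (-3.0 * dA_dz**2 / A * s1 + d2A_dz2 * s2)
    )
    leading = alpha**2 * beta_prefactor(beta) * d2A_dz2
    return full, leading


#: analytic circular-duct slope of the percent-error line, -100/(6π)
ANALYTIC_SLOPE = -100.0 / (6.0 * np.pi)


@dataclass(frozen=True)
class CorrectionModel:
    """Linear model err% = slope·A'' + intercept for the series-unidirectional
    error, and the induced multiplicative correction λ = 100/(100 + err%).

    ``realistic`` and ``circular`` carry coefficients fitted against 3D
    simulations of murine pial perivascular segments and their
    area-matched circular ducts; ``analytic`` is the extended-lubrication
    prediction for circular ducts.
    """

    slope: float
    intercept: float
    kind: str = "custom"

    @classmethod
    def realistic(cls) -> "CorrectionModel":
        return cls(slope=-1.8, intercept=-3.2, kind="realistic")

    @classmethod
    def circular(cls) -> "CorrectionModel":
        return cls(slope=-4.4, intercept=0.22, kind="circular")

    @classmethod
    def analytic(cls) -> "CorrectionModel":
        return cls(slope=ANALYTIC_SLOPE, intercept=0.0, kind="analytic")

    @classmethod
    def from_kind(cls, kind: str) -> "CorrectionModel":
        try:
            return {"realistic": cls.realistic, "circular": cls.circular,
                    "analytic": cls.analytic}[kind]()
        except KeyError:
            raise ValueError(f"unknown correction model {kind!r}") from None

    def err_percent(self, d2A_dz2) -> np.ndarray:
        return self.slope * np.asarray(d2A_dz2, float) + self.intercept

    def lambda_factor(self, d2A_dz2) -> np.ndarray:
        """λ(A'') = 100 / (100 + slope·A'' + intercept)."""
        denom = 100.0 + self.err_percent(d2A_dz2)
        if np.any(denom <= 0.0):
            bad = np.asarray(d2A_dz2, float)[np.asarray(denom) <= 0.0]
            raise ValueError(
                f"lambda <= 0 at d2A/dz2 = {bad}: correction model "
                f"'{self.kind}' used outside its validity range"
            )
        return 100.0 / denom


def lambda_correct(
    profile: ResistanceProfile,
    d2A_dz2: np.ndarray | None = None,
    model: CorrectionModel | str = "analytic",
) -> ResistanceProfile:
    """Apply the λ correction to a series-unidirectional profile.

    ``d2A_dz2`` defaults to the values stored on the profile.  The returned
    profile is tagged "<method>·λ".
    """
    if isinstance(model, str):
        model = CorrectionModel.from_kind(model)
    if d2A_dz2 is None:
        if profile.d2A_dz2 is None:
            raise ValueError("profile carries no d2A/dz2; pass it explicitly")
        d2A_dz2 = profile.d2A_dz2
    lam = model.lambda_factor(d2A_dz2)
    return profile.with_values(profile.R_local * lam, profile.method + "·λ")
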