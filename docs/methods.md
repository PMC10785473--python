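# Methods

`pvsflow` estimates the hydraulic resistance per unit length,

    R(z) = -(∂p/∂z) / Q        [Pa·s/µm⁴],

of long, narrow ducts whose cross section varies along a centerline — the
geometry of pial perivascular spaces (PVSs), the CSF-filled channels around
brain surface arteries. Flows there have Reynolds and Womersley numbers far
below one, so steady Stokes flow is solved throughout; resistance is then
independent of the flow rate, and all estimators work per unit viscosity.

## Model hierarchy

**Series-unidirectional (uniform-duct) estimators.** The duct is treated as
a chain of uniform ducts, one per cross section, each carrying purely axial
flow. The axial momentum balance reduces to a Poisson problem
µ∇²w = dp/dz on the section with no-slip walls, solved:

* numerically (**SUN**) with linear finite elements on a Delaunay
  triangulation of the polygon (see *Numerics*), R = |dp/dz| / ∫w dA;
* analytically (**SUA**) for circles: R = 8µ/(πr⁴) (Hagen–Poiseuille).

**Fast closed-form approximations** of the per-section result:

* **Method I** — area scaling from one reference section,
  R_I = R_ref (A_ref/A)²; exact when the shape is self-similar along the
  duct (at fixed aspect ratio the elliptical result is ∝ A⁻²).
* **Method II** — shape factor, R_II = 8µγ/(π r_eq⁴) with
  γ = (1/N) Σ (r_eq/d_j)⁴ over N equally spaced boundary points at
  distances d_j from the interior point minimizing γ. The optimal center,
  not the centroid, is used: for sections that narrow at the middle the
  centroid badly overestimates the resistance.
* **Method III** — elliptical lubrication result with the matched-ellipse
  aspect ratio β (the ellipse sharing the section's central second
  moments): R_III = 4µ(β²+1)/(π r_eq⁴ β).
* **Method IV** — polar-moment form R_IV = 16π²µ I_p / A⁴.

Methods III and IV are algebraically exact for true ellipses (this is the
module's primary oracle) and all methods reduce to Hagen–Poiseuille on
circles.

**Extended lubrication theory (ELT).** For a nonuniform elliptical duct
with semi-axes b(z), c(z), a second-order expansion in the duct's
transverse/axial aspect ratio gives a correction R₂ to the uniform-duct
resistance R₀ = 4µ(b²+c²)/(πb³c³), depending on b′, c′, b″, c″; the total
is R₀ + R₂ (in dimensional variables the formal expansion parameter is
absorbed into the axial derivatives). For self-similar ducts (dβ/dz = 0)
R₂ collapses to a form needing only A, A′, A″. The implementation of the
general form is verified symbolically: the cross-section average of the
pointwise second-order pressure gradient equals −Q·R₂ (a sympy identity
kept as a regression test), and numerically against the hand-derived
linear-taper value R₂ = −16µs²/(3πr⁴).

The fractional error of the uniform-duct approximation predicted by ELT is
dominated by the area curvature:

    E ≈ P(β)·A″,   P(β) = (β⁴+14β²+1)/(48πβ(β²+1)),   P(1) = 1/(6π),

with P(β) = P(1/β) and within 13.3% of P(1) for β < 7. Expressed as a
percent-error line err% ≈ slope·A″ + intercept (err = (R_SU−R_true)/R_true),
the circular-duct slope is −100/(6π) ≈ −5.3 per unit A″.

**λ correction.** Inverting the error line gives a multiplicative
correction λ(A″) = 100/(100 + slope·A″ + intercept) applied per station to
a series-unidirectional profile. Three coefficient sets are built in:
`analytic` (−100/(6π), 0), and `realistic` (−1.8, −3.2) / `circular`
(−4.4, 0.22), which are published fits against 3D simulations of murine
pial PVS segments and their area-matched circular ducts. λ must stay
positive over the duct's A″ range; values outside the fit's validity raise.

**Axisymmetric Stokes oracle.** For circular ducts of varying radius, the
ground truth is a steady axisymmetric Stokes solve in primitive variables
(u_r, u_z, p): stabilized P1–P1 finite elements (Brezzi–Pitkäranta) on a
boundary-fitted structured triangulation using the mapped radial
coordinate η = r/R(z). Boundary conditions: prescribed parabolic inflow at
rate Q, no slip at the wall, symmetry at the axis, traction-free outlet.
The resistance profile mimics 3D post-processing: a 40 µm uniform entrance
duct is prepended (covering the creeping-flow entrance length
z_L ≈ 0.5 D_h for PVS-scale sections; for much wider ducts the prescribed
fully developed inflow makes the entrance a buffer for upstream influence
of the first wall undulation), pressures are volume-weighted (2πr) in
2-µm axial slices, adjacent slice means are differenced and divided by Q,
and the last five stations are excluded from averages (exit effects; the
count is a parameter).

## Validation against an exact solution

The solver is cross-checked against the exact first-order solution for
Stokes flow in a corrugated tube a(z) = a₀(1+ε sin kz): in modified Bessel
functions, the local slice-averaged resistance responds as
δR/R₀ = T(x)·ε·sin kz with x = k·a₀ and

    T(x) = −2x I₁(x)² / (2I₀(x)I₁(x) + x(I₁(x)² − I₀(x)²)).

T → −4 as x → 0 (uniform-duct limit) and the error coefficient −4−T(x)
→ −x²/3, which is exactly the second-order lubrication prediction. The
finite-element solver matches T(x) to ≤1% at x = 0.70 and x = 2π
(`wavy_tube_response`, tested by harmonic fits over integer periods).

This closed form also delimits where the lubrication error model is
trustworthy: at x = 2π the true response coefficient is 8.75 versus the
lubrication value 13.16, i.e. extended lubrication **overpredicts the
uniform-duct error by ~50% for corrugations whose wavelength is comparable
to the radius**. Consequently, for the sinusoidal benchmark duct
r = 50 + 1.5 sin(2πz/50) µm (x = 2π):

* the regression slope of the per-station percent error on A″ is −3.4
  (exact linearized value −3.53), not the slender-duct −5.3, and
* the `analytic` λ correction removes only ~15% of the RMS deviation from
  the Stokes solution.

Two acceptance tests assert the slender-duct expectations on this duct and
are deliberately left failing as an honest record of this limit. At
PVS-scale wavenumbers (r₀ ≈ 5.6 µm, 50 µm wavelength, x ≈ 0.7) the same
pipeline recovers slopes near −5.3 and the λ correction removes 54–79% of
the RMS deviation, and ELT captures the majority of the uniform-duct
deviation — the regime the published fits (−4.4 for circularized murine
ducts, x ≈ 0.7–2) actually occupy.

## Synthetic geometries

* **Sinusoidal circular duct** (defaults r₀ = 50 µm, amplitude 1.5 µm,
  wavelength 50 µm, length 100 µm = two periods, stations every 0.7 µm):
  the benchmark for unidirectional-flow error.
* **Nonuniform elliptical ducts** b(z), c(z) with analytic derivative
  callbacks, for lubrication cross-checks.
* **Bi-lobe ducts**: one crescent lobe of (outer ellipse − vessel disk),
  emulating pial PVS lobes — single-lobe, partly concave sections. The
  default spec (vessel radius 12 µm, ellipse axes 1.7× and 0.8× that) was
  calibrated once to the observed summary statistics: mean area ≈ 110 µm²
  (target ~100 µm²) and matched-ellipse β ≈ 1.5–1.8 (observed range
  1.1–2). Axial variation is a sinusoidal modulation of the ellipse axes
  (±6%, 50 µm wavelength) plus three seeded low-frequency random modes
  (2%); perturbing the generating conics rather than the polygon keeps
  every section simple by construction. One integer seed makes ducts fully
  reproducible.
* **Perturbed-ellipse sections**: ellipses with smooth random boundary
  harmonics (wavenumbers 2–5, 2.5% amplitude) — "bumpy but not oblong"
  sections for shape-factor studies.

What the generators do **not** emulate: segmentation noise and voxel
staircase artifacts, curvature of real centerlines (the Dean number
De = Re√(r_e/r_c) ≈ 2.5×10⁻⁴ shows curvature is negligible for resistance,
and a circumradius-based r_c(z) diagnostic is provided), azimuthally
localized wall features, and the full shape statistics of real PVSs.
Passing tests therefore demonstrate correctness of the numerics and of the
closed-form theory on idealized geometry, not fidelity to any particular
animal's anatomy.

A finding from this synthetic suite: thin, strongly curved crescents can
have a matched-ellipse axis ratio near 1 while behaving nothing like a
circle — Method II errors reach −18% at 1/β > 0.7 for such shapes. The
"error < 10% when 1/β > 0.7" rule holds for moderately concave, bumpy
sections; β is a poor oblongness proxy for extreme crescents.

## Numerics

* **Cross-section meshing** (SUN): boundary resampled to the target edge
  length h, interior points on a hexagonal lattice kept ≥ 0.4h from the
  wall, Delaunay triangulation filtered by centroid containment (handles
  concave lobes). Default h = r_eq/24, set by the circle benchmark: the
  error against Hagen–Poiseuille is ~0.11% at default resolution
  (criterion: 0.5%), decreasing monotonically under refinement; ellipse
  benchmarks (β = 1.5–3) are within 0.2%. `mesh_size` is exposed and the
  achieved circle error is logged by the CLI.
* **Polygon metrics**: exact shoelace formulas for area, centroid and
  second moments; β = √(λ₁/λ₂) from the central second-moment tensor's
  eigenvalues; verified against Monte-Carlo integration (0.5%).
* **Area profile derivatives**: A(z) is cubic-spline interpolated onto a
  uniform grid (default 0.7 µm) and differentiated by second-order central
  differences (one-sided, second-order at the ends) — exact for quadratic
  A(z). Optional boxcar smoothing (off by default) is recorded on the
  duct; how much smoothing segmented data needs is an open, data-dependent
  choice, so it is explicit rather than implicit.
* **γ minimization** (Method II): Nelder–Mead polished from both the
  centroid (or a representative interior point when the centroid lies
  outside, as for crescents) and the best of a 12×12 interior grid scan —
  γ is multimodal for bi-lobed shapes and a symmetric start can sit on a
  saddle. Boundary points are resampled to equal arc length (default
  N = 100) to remove vertex-density bias; γ is scale invariant.
* **Axisymmetric solver**: structured quadrilateral grid split into
  triangles, 3-point interior quadrature (never touching r = 0); pressure
  stabilization δ Σ h_T²/µ (∇p,∇q) r dA with δ = 0.05. The axial spacing
  is snapped so each 2-µm slice spans a whole number of element layers —
  incommensurate bins alias the slice averages. Default resolution 41
  radial nodes, ~0.67 µm axial spacing: Poiseuille within 0.12%, flux
  conserved to 0.03% at every station, grid-halving changes the average
  resistance by < 0.1%.
* **Degenerate inputs**: polygons with < 3 vertices, non-positive area or
  self-intersections raise a dedicated geometry error (clockwise input is
  re-oriented); non-monotone stations, non-circular ducts passed to SUA or
  the oracle, and λ ≤ 0 (fit used outside its range) raise with context.

## Units and reporting

Lengths in µm, viscosity in Pa·s, flow in µm³/s, resistance per unit
length in Pa·s/µm⁴. Default µ = 6.9×10⁻⁴ Pa·s (water at 37 °C) and
Q = 2.19×10⁴ µm³/s (typical pial PVS flow); resistances are
viscosity-proportional, so printed values must always be read with µ.
Profiles can be written in mmHg·min/mL/m via the single constant
10¹⁸/(133.322·60) ≈ 1.2502×10¹⁴. Comparison tables report signed average
and RMS percent error with the reference method as the percentage base
(Stokes-solution base for oracle comparisons, SUN base for quick-method
comparisons).

## Known limitations

* The oracle covers only circular ducts (axisymmetric flow); general 3D
  non-axisymmetric solves are out of scope, so absolute-error tables for
  realistic lobed geometries cannot be reproduced here.
* ELT and the `analytic` λ model degrade once the corrugation wavelength
  approaches the duct circumference (x ≳ 2), as quantified above; the
  fitted `realistic`/`circular` coefficients inherit the geometry mix they
  were fitted on.
* The λ ≤ 0 guard limits the fitted models to |A″| within their fitted
  range (about A″ < 22 for `circular`).
* Bi-lobe realism is best-effort summary-statistics matching, not a model
  of any measured PVS.
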