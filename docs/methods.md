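# Methods

## Model overview

`vertefem` simulates displacement-controlled axial compression of an
isolated vertebral body. The mechanical model is deliberately the standard
QCT-FE recipe: per-element isotropic linear elasticity with density-mapped
modulus, associative J2 (von Mises) perfect plasticity for the post-yield
response, small-strain kinematics, and constant-strain tetrahedra. Failure
is read from the accumulated equivalent plastic strain (PEEQ), not from
element deletion or crack propagation.

## Density calibration

Apparent density follows the linear attenuation map ρ = a + HU·b with a
floor of 0.01 g/cm³ applied after the linear map, which guarantees the
stated minimum regardless of calibration constants. Defaults are
a = 0.48 g/cm³ and b = 4.6·10⁻⁴ g/cm³/HU. The slope deserves a note: the
constant is sometimes quoted with a positive exponent (4.6·10⁴), which
would produce densities of ~10⁷ g/cm³ at a few hundred HU; `vertefem`
treats that as a sign-of-exponent typo, defaults to 4.6·10⁻⁴, logs the
assumption whenever the default line is instantiated, and leaves both
constants overridable. The fit to core samples is unweighted ordinary least
squares. Air (−1000 HU) is excluded by the bone mask before calibration,
so the floor is only exercised by genuinely low in-mask attenuation.

## Material mapping

With ρ in g/cm³ and stresses in MPa (lengths in mm, so forces come out in
newtons):

    E   = 3050 ρ^1.81
    ε_y = s · 0.0065 ρ^−1.42
    σ_y = E ε_y           (so σ_y ∝ ρ^0.39, increasing in ρ)
    ν   = 0.3

The dimensionless yield-strain scale `s` (default 1.0) multiplies ε_y and
σ_y linearly and leaves E untouched; the value calibrated against porcine
bench tests is 3.1. The units of E and ρ are conventional for this family
of power laws; the laws are applied to apparent density directly. An
apparent/ash density ratio is exposed (`ash_ratio`, default 1.0 = off)
because the literature states a ρ_app/ρ_ash = 0.6 conversion without fixing
where it enters — note the quoted direction implies ρ_ash > ρ_app, which
inverts the usual convention, so neither direction is active by default and
the printed anchor E(1.0 g/cm³) = 3050 MPa stays reproducible. Materials
are isotropic; no strain-rate dependence, damage or softening is modelled,
and perfect plasticity means an exactly zero hardening modulus.

Element densities come from the voxel each element was carved from;
optional binning buckets densities into uniform-width bins and evaluates
one card per bin at the bin-mean density (the discrete assignment typical
of QCT pipelines).

## Phantoms

The synthetic vertebral body is an elliptical cylinder (default semi-axes
14 mm anteroposterior × 11 mm mediolateral, height 22 mm — lower-thoracic
porcine proportions) whose in-plane semi-axes shrink cosine-smoothly to a
waist (default 85 %) at mid-height. A lateral cortical shell (default 2 mm,
1300 HU) surrounds a trabecular core whose HU field is a seeded Gaussian
random field smoothed over a 3-voxel kernel (mean 350 HU, sd 60 HU);
smoothing keeps per-element densities well-posed. Endplates are flat,
emulating polished, plate-cut specimens. **All HU defaults are
plausible-but-invented**: no quantitative HU statistics of real specimens
stand behind them, so absolute stiffness/strength of the phantom are not
calibrated to any real vertebra (the worked example's 29 kN/mm is
accordingly stiffer than typical bench values near 9.5 kN/mm). What the
phantom does reproduce is the *structure* of the problem: cortical/
trabecular contrast, heterogeneity, waisted geometry, and flat loading
surfaces.

The synthetic "experiment" generator draws per-specimen stiffness and
strength from normals truncated at zero — defaults 9.54 ± 1.1 kN/mm and
10.2 ± 0.86 kN, the dispersion reported for bench compression of porcine
T12–T14 bodies — and emits bilinear curves (linear ramp, plateau at the
strength) on a fixed displacement grid. It emulates summary dispersion
only: no toe region, no post-peak softening, no measurement noise along
the curve. Tests that pass on these curves therefore validate the
extraction and comparison machinery, not the realism of any particular
experimental rig.

Coordinate convention throughout: axis 0 mediolateral, axis 1
anteroposterior (anterior +), axis 2 axial (cranial +); voxel centers at
`origin + (index + 0.5)·spacing`.

## Meshing

Each masked voxel is subdivided into the six tetrahedra of the Kuhn
triangulation (all six share the voxel's main diagonal). Because the same
template is applied to every voxel, face diagonals agree across voxel
boundaries and the mesh is conforming by construction; the partition is
exactly volume-preserving (6 tets × V/6). Edge lengths track the voxel
size, so ~1 mm voxels give the ~1 mm T4 edges of the reference modelling
practice. The staircase boundary this produces is accepted and documented:
it stiffens the surface slightly and is the main reason phantom stiffness
converges only as voxels shrink. Node deduplication is exact through the
structured corner grid (a 10⁻⁶ mm tolerance applies to externally loaded
meshes).

Cranial/caudal surfaces are boundary faces whose outward normal lies
within 30° of ±axial and whose centroid sits in the outer 10 % of the
axial extent. The transverse plane is the average of the two best-fit
surface planes; the center of mass is density-weighted; "body width" is
the anteroposterior node-cloud extent (the mediolateral reading of
"width" is selectable via the frame's directions but anteroposterior is
the default, since the anterior offset along it is what produces the wedge
mode).

## Load cases

**Follower mode** (the production configuration): the control point is the
projection of the center of mass onto the cranial plane, displaced
anteriorly by 10 % of the body width (configurable). Cranial nodes are
rigid slaves of the control point via linearized rotations
(u_i = u_c + θ × r_i), realized by master–slave elimination — no Lagrange
multipliers, no over-constraint. The control point's transverse
translations are locked, its three rotations are free (no rotation cap is
imposed), and the caudal surface is fully fixed. The default schedule
compresses by one third of the axial extent — the conventional failure
displacement for this test — in 40 equal increments.

**Uniaxial mode** (verification): only axial displacements are prescribed
on the end surfaces, with a statically determinate 3-2-1 lateral support
on the caudal surface. A homogeneous bar is then an exact uniaxial-stress
state: constant-strain tetrahedra reproduce stiffness EA/L and the plastic
limit load σ_y·A to machine precision, which the test suite asserts.

## Solver numerics

* **Return mapping.** Closed-form radial return: trial deviator scaled to
  the yield surface, ΔPEEQ = (q_tr − σ_y)/(3G), hydrostatic part
  untouched. Uniaxial stress states reproduce the bilinear law
  σ = Eε / σ_y exactly.
* **Consistent tangent.** D = K·1⊗1 + (2Gσ_y/q_tr)·I_dev −
  (3Gσ_y/q_tr³)·s⊗s, the exact linearization of the return-mapped stress.
  It is positive semi-definite with a zero eigenvalue along the flow
  direction, so the Newton matrix adds a 10⁻⁹ fraction of the elastic
  stiffness; convergence is judged on the true residual, leaving the
  converged solution unaffected.
* **Globalization.** Each increment minimizes a convex C¹ incremental
  potential (elastic energy with a Huber-type deviatoric term beyond
  yield) whose gradient is the internal-force residual. Newton directions
  are therefore descent directions, and an Armijo backtracking line search
  on that energy makes the iteration globally convergent — including at
  the limit load, where residual-based line searches stall.
* **Cutback.** A failed increment is retried in halved substeps (each
  converged substep is committed) down to 1/16 of the scheduled step;
  only then is a partial record returned with an explicit failure flag.
* **Warm start.** Increments start from a secant extrapolation of the two
  previous converged states, which roughly halves Newton iterations.
* **Tolerances.** Relative residual 10⁻⁶ (absolute fallback 10⁻⁸ N),
  25 iterations per Newton solve, direct sparse LU for the reduced system.
* Reactions are accumulated in newtons and reported on curves in kN;
  the compressive reaction is the work conjugate of the prescribed
  compression magnitude.

Kinematics are geometrically linear: the nonlinearity is material only.
At the default failure displacement (a third of the body height) true
strains are finite, so the recorded deep-collapse branch should be read
qualitatively; stiffness and strength are extracted near the knee, where
small-strain theory is adequate.

## Post-processing

Stiffness is the OLS slope over ascending-branch points whose load lies in
20–80 % of the peak (the window is configurable and recorded — the
"linear trajectory" has no canonical definition, so the window realizes
it reproducibly). Strength is the curve maximum; for an
elastic–perfectly-plastic solve this coincides with the highest point of
the elastic response at plateau onset. Experimental CSV curves flow
through exactly the same extractors. The fracture map thresholds final
PEEQ at 10⁻⁸ (zero reproduces the literal "nonzero plastic strain" rule;
the default absorbs round-off) and labels element centroids into sectors
about the axial axis through the center of mass with a 45° anterior/
posterior half-angle — the sector geometry is a reporting choice, as the
reference failure descriptions are qualitative.

## Comparison and calibration

The coefficient of determination is the squared Pearson correlation
(equivalent to regression R² for a simple linear fit; a constant
prediction is assigned R² = 0). Percent errors are absolute. The
yield-strain scale is calibrated by bounded scalar minimization of the
mean absolute strength percent error, warm-started at
mean(experimental / predicted-at-scale-1) — justified because the
perfectly plastic limit load is linear in the scale. Stiffness is reported
but not optimized: the scale cannot change the elastic slope.

## Problem sizes used in the shipped tests

The suite runs on coarse phantoms chosen as the smallest meshes that still
exhibit every qualitative feature (cortical/trabecular contrast, waist,
anterior wedge pattern): 2–2.5 mm voxels, roughly 2–6 thousand elements,
8–20 increments, three specimens for the scale-recovery study. The
verification bar is 10 × 4 × 4 mm at 1 mm voxels. Production runs at
~1 mm voxels (10⁵–10⁶ elements) use the identical code paths.

## Known limitations

* Staircase surfaces; no smooth surface reconstruction or posterior
  elements (real specimens have their posterior elements removed anyway).
* Small-strain, geometrically linear kinematics; no contact, discs or
  multi-vertebra constructs.
* Perfect plasticity cannot reproduce post-peak load drops; "failure" is
  a plastic-strain map, not a crack geometry.
* Phantom HU statistics are invented; absolute phantom stiffness/strength
  are not calibrated to any real specimen population.
* The HU→density line is scanner-specific in reality; no phantom-rod
  scanner calibration or nonlinear calibration forms are provided.
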