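# Methods

`lungmech` models respiration-induced lung tumor motion and deformation
(LTMD) with a patient-specific, time-varying hyperelastic finite-element
model, recovers per-phase lung elasticity from tumor motion, and analyzes
the surface forces that drive it. This note documents the model, its
assumptions, the numerical choices, and what the synthetic phantom does and
does not emulate.

## Biomechanical model

The lung is an isotropic, homogeneous hyperelastic continuum within each
respiratory phase; the tumor is a stiff inclusion (E = 49 MPa, v = 0.4)
carried passively by the surrounding tissue. Two compressible strain-energy
densities are available,

- Saint-Venant–Kirchhoff (SVK): `W = λ/2 tr(E)² + μ tr(E²)`,
  `E = (FᵀF − I)/2`,
- Neo-Hookean (NH): `W = μ/2 (I₁ − 3) − μ ln J + λ/2 (ln J)²`,
  `I₁ = tr(FᵀF)`, `J = det F`,

with Lamé parameters `λ = vE/((1+v)(1−2v))`, `μ = E/(2(1+v))`. The model is
selected per patient from the inhale/exhale lung volume ratio
`J = V(P00)/V(P50)`: SVK for `J ≤ 1.1` (boundary inclusive), NH above —
SVK is accurate at moderate strain, while NH's logarithmic volumetric term
remains well-behaved at the larger volume changes.

Breathing is quasi-static: registration-derived surface displacement fields
are Dirichlet data on the lung surface, no body forces (supine gravity and
cardiac motion are out of scope), and interior lung plus tumor nodes
equilibrate by minimizing total strain energy. The tumor is modeled with the
SVK law at its stated stiffness; at the ~1e-4 strains a 49 MPa inclusion
experiences inside 2–11 kPa lung, SVK is numerically indistinguishable from
linear elasticity.

### Discretization and solver

Linear 4-node tetrahedra with single-point quadrature. Element residuals and
the exact consistent tangent (`∂P/∂F` in closed form for both laws) are
assembled vectorized; Newton–Raphson with Armijo backtracking and
displacement-increment continuation (default 5 increments; phantom studies
use 2, sufficient for the ≤ 40 % volume changes considered) solves each
transition. Convergence: residual norm below `tol × (stiffness diagonal ×
boundary displacement scale)`, default `tol = 1e-10`, which drives the
affine patch test to machine precision.

Known caveat: single-point linear tets lock volumetrically as v → 0.5.
Accuracy statements are made for v ≤ 0.45; the physiological search box
[0.1, 0.49] touches that regime only at its upper edge. This also bounds the
small-strain linearization check: the exact second-order SVK term scales as
`strain × λ/μ` (~2 % at v = 0.49, strain 1e-3), so the 1 % agreement with
Hooke's law is verified for v ≤ 0.45.

### Cycle propagation

The gross tumor volume is propagated through
P50→P60→…→P90→P00→…→P40→P50. Default scheme (`reference="observed"`): each
transition is solved on the observed phase-i mesh (mirroring per-phase
remeshing from registration), and the converged displacement updates the
propagated tumor nodes. This keeps every solve anchored to observation;
an exactly cyclic phantom closes the loop to ~0.05 mm. The alternative
`"accumulated"` scheme feeds each solution forward as the next reference;
it accrues re-referencing hysteresis (~0.1 mm/cycle at default resolution,
growing when materials vary per phase) and is retained for sensitivity
studies.

## Validation metrics

ΔTCM is the Euclidean distance between simulated and observed tumor
centroids (mesh-based, hence sub-voxel). vDSC rasterizes both tumor meshes
on a shared grid (default voxel `min(1 mm, diameter/20)`; halving the voxel
moves values by < 0.005) and computes `2|A∩B|/(|A|+|B|)`. D-vDSC — whose
construction the source material leaves open — is defined here as vDSC after
translating the simulated tumor so the centroids coincide, isolating shape
change from bulk motion.

## Inverse elasticity estimation

Per phase transition, (E, v) minimizes `ΔTCM + (1 − vDSC)` over
E ∈ [2, 11] kPa, v ∈ [0.1, 0.49]. The two addends are summed unnormalized
(millimetres against fractional overlap), as printed in the source model;
the weighting only rescales the objective and does not move its minimizer.
Efficient Global Optimization: Latin-hypercube initial design (8 points), a
GP surrogate (anisotropic RBF, nugget 1e-10, inputs scaled to the unit
square, outputs normalized), expected improvement (ξ = 0.01) maximized over
4096 scrambled-Sobol candidates plus 256 local perturbations of the
incumbent (σ = 0.05 in unit-cube units — added because the objective is
extremely anisotropic, see below). Stopping: improvement < 0.01 over 10
consecutive iterations, or 500 iterations. A transition whose initial
design shows an objective range below tolerance (e.g. zero displacement) is
flagged non-identifiable rather than over-fit.

### Identifiability

A structural property of this experiment worth stating plainly: with purely
Dirichlet surface driving, scaling the strain energy `W → cW` leaves the
equilibrium displacement unchanged, so the objective depends on lung E only
through the lung/tumor stiffness contrast. At 49 MPa the tumor is
effectively rigid against any lung E in the box (contrast 4.5e3–2.5e4), and
the measured objective variation along E at the true v is ~1e-5 mm — versus
~1 along v. Poisson's ratio is therefore recovered to ±0.002 in the
self-consistent phantom experiment while Young's modulus is essentially
unconstrained by tumor motion alone. The GP reflects this honestly (the
fitted E length-scale runs to its bound). Identifying E would require force
or pressure data, a compliant tumor, or an objective term beyond the tumor
region.

## Temporal models

Four families fit the per-phase samples (t, E) and (t, v): Exp2, Fourier1
(`c₁cos(c₂t) + c₃sin(c₄t) + c₅`, independent frequencies as printed, with a
single-frequency option), Gauss2, Poly2. Poly2 is closed-form; the others
use 16 seeded multi-starts of Levenberg–Marquardt-type least squares with
frequency/width starts at the breathing cycle and its harmonics. R² is
computed on the fitted samples only; constant samples with zero residual
take R² = 1 by convention. Ranking: R² descending, ties by MSE, then fewer
coefficients.

## Surface traction fields

Nominal traction on the undeformed lung surface: `T = P n₀` per boundary
face, with P from the single adjacent tet (piecewise-constant stress), plus
Cauchy stress `σ = J⁻¹ P Fᵀ` and the angle θ between T and the outward
normal. Because the piecewise-constant face stress satisfies global
equilibrium only to O(h) (~0.1 at 2k tets), the field also carries the
energy-conjugate *consistent* traction recovered from the Dirichlet
reaction forces (area-lumped onto faces so that `Σ T·dA` equals the nodal
reaction sum exactly); equilibrium accounting uses that flux, which
vanishes to solver tolerance. Directional summaries average |T| and θ over
faces within a 10° cone around rays from the end-expiration tumor centroid
toward the true/simulated end-inspiration centroid and the nearest surface
point; an empty cone (coarse mesh) falls back to the best-aligned face.

On the amplitude-graded phantom cohort, traction amplitude along the motion
direction correlates strongly and positively with tumor motion amplitude
(r ≈ 0.99 at 15 cases). The traction *angle* correlation is
geometry-dependent: this phantom produces a positive angle–motion
correlation, whereas patient anatomy can produce the opposite sign; the
phantom makes no claim about that sign.

## Features and regression

Eleven per-case features (volume, mean-HU, bounding-box and
surface-to-volume changes between P00 and P50; age; lung motion amplitude;
BMI; ADI and SRI from the principal stretches of the volume-averaged lung
deformation gradient, via polar decomposition) feed a two-step LASSO
against cycle-averaged E and v. Both steps use leave-one-out CV on a grid
of 50 log-spaced penalties spanning `[1e-4, 10] ×` the max-correlation
scale. Step 1 (selection) uses the one-standard-error rule by default: the
MSE-minimizing penalty is known not to be selection-consistent — on
constructed cohorts it retains spurious features in about half of the
replicates at *any* noise level, and an independent glmnet run reproduces
this — while the 1-SE rule recovers the planted sparse support reliably.
Step 2 refits the selected subset at its own MSE-minimizing penalty.
Features are standardized internally; coefficients are reported on the
standardized scale.

"Deformation tensor" for ADI/SRI is interpreted as the right stretch tensor
U of the volume-averaged F (its eigenvalues are positive, which the ratio
formulas require). SRI limits: λ₁ = λ₂ → 0, λ₂ = λ₃ → 1.

## Synthetic phantom

An ellipsoidal lung (semi-axes 50 × 70 × 100 mm, ~1.5 L) with an embedded
spherical tumor (r = 10 mm, ~4.2 cm³, caudal offset) breathes through 10
phases of a 4 s cycle under the map `u(x, t) = s(t)·d(x)` with
`s(t) = (1 + cos 2πt/T)/2` — P00 is end-inspiration, P50 the undeformed
end-expiration reference. `d(x)` is an anisotropic dilation (axis weights
0.25 : 0.25 : 1, dominated by the cranio-caudal axis) plus a caudally graded
axial term emulating diaphragm drive. The grading integrates to zero over
the ellipsoid, so the inhale volume ratio is prescribed exactly by the
dilation (default 13 % change; 7–39 % supported). The default caudal
amplitude of 8 mm yields ~6 mm tumor motion. Ground-truth E(t), v(t) are
first-order Fourier series inside [2, 11] kPa × [0.1, 0.49], so the
temporal stage can recover them exactly noise-free. Optional Gaussian
perturbation of the surface fields emulates registration error.

Meshing: icosphere surface vertices plus an interior jittered lattice,
Delaunay-triangulated (the ellipsoid is convex, so the triangulation fills
it exactly); tets are labeled tumor by centroid containment. Default edge
length 16 mm gives ~2200 tets — the working resolution of all phantom
studies, chosen because the tumor centroid displacement changes by < 0.5 %
on refinement to ~4700 tets.

What the phantom does **not** emulate: real lobar anatomy, pleural sliding,
heterogeneous elasticity, hysteretic breathing (inhale and exhale follow
the same spatial path), imaging noise or registration artifacts beyond
additive Gaussian surface noise. One consequence is worth flagging: the
caudally graded map is kinematic truth but not an elastic equilibrium
field, so the FEM interior legitimately deviates from it (~2 mm in tumor
centroid at default amplitude). Analytic-map oracles are therefore applied
to the affine phantom (`displacement_amplitude = 0`), where the map *is*
the equilibrium; for graded phantoms the forward FEM solution defines the
observation truth (the standard self-consistent inverse experiment).
Passing phantom tests demonstrates internal consistency of the chain, not
clinical accuracy.

## Degenerate inputs and conventions

Inverted tets are repaired by vertex swap at construction; surfaces must be
closed and outward-oriented (checked, with offending edges reported).
Zero-variance temporal samples take R² = 1 when residuals vanish. A
constant LASSO target or an all-failed EGO design raise errors. Meshes are
in DICOM LPS millimetres with 0-based indices; MSH v2.2 physical tags 1/2
and a VTK cell field `region` (0/1) carry the lung/tumor labels.

## Problem sizes

Default study sizes: ~2200-tet phantoms, 10 transitions per cycle, ≤ 100
objective evaluations per inverse recovery, 15-case traction cohorts,
30-case × 20-seed LASSO cohorts. These are the sizes at which the reported
checks were computed; all scale up linearly through configuration.
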