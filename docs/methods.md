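# Methods

`arterysim` simulates tension–inflation tests on a two-layer arterial
segment with a multiscale hypoelastic constitutive description of the
adventitia. This note records the model, its numerical treatment, the
choices made where the design was genuinely open, and the limits of what
the test suite demonstrates.

## Structural model

The artery is an initially unloaded hollow cylinder (outer radius `R_o`,
wall thickness `δ_o`, length `L_o`) of two concentric layers: the media
(inner, thickness `δ_M`), treated as a homogeneous isotropic hypoelastic
solid (`E_M = 0.12 MPa`, `ν_M = 0.49`), and the adventitia (outer,
`δ_A = δ_o − δ_M`), which carries the collagen microstructure. The loading
is quasi-static: an inner pressure applied as a follower load on the
current inner surface, and an axial displacement imposed on one end
section while the other end is fully clamped. Two protocols are built in:

* **S-test** — ramp the pressure to a held value (20/100/140 mmHg in steps
  of `ΔP = 5 mmHg`), then ramp the axial stretch λ from 1 to 1.8 in steps
  of `Δλ = 0.03`;
* **P-test** — ramp the stretch to a held value (1.5 or 1.8), then the
  pressure from 0 to 140 mmHg.

All output quantities are averaged over the central region (axial span
L/4 at mid-length) to avoid the clamped-end boundary layers.

## Adventitial micromechanics

Each adventitial material point carries a representative volume element:
an isotropic matrix (`E_m = 10 kPa`, `ν_m = 0.4`; the elastin network is
subsumed in the matrix stiffness) containing `n = 4` families of
infinitely long cylindrical collagen inclusions that share the collagen
volume fraction `f_c` equally. Family orientations are tracked by a triad
(fiber axis `c` and two transverse vectors) tied to the local wall frame
(K, T, N) = (circumferential, axial, radial) through Euler angles (φ, θ);
θ = 0 is the axial direction.

Phase strain rates and spins are linear in the macroscopic strain rate D
applied to the RVE boundary:

    d_i = A_i : D ,      w_i = R_i : D .

The strain-rate concentrations `A_i` follow the Mori–Tanaka scheme built
on the interior Eshelby tensor of an infinite circular cylinder (computed
from the transverse line integral of the Green operator; for an isotropic
matrix the integrand is a low-order trigonometric polynomial, so the
64-point periodic trapezoid rule is exact to machine precision). The spin
operator uses the antisymmetric part of the same interior-gradient
operator Π: with the equivalent eigenstrain of the Eshelby equivalence
condition, `R_i = −Π : C_m⁻¹ : (C_i − C_m) : A_i^MT`. Identical phases
yield zero spin; a stiff fiber inclined to a uniaxial stretch rotates
toward the stretch axis, which fixes the sign convention and is verified
in the tests together with the concentration sum rule
`Σ_r f_r A_r = I` (machine precision at every Gauss point, every step).

All phases are hypoelastic with Jaumann (corotational) stress rates. The
homogenized adventitial tangent converts each phase's Jaumann rate to a
material rate using the current phase stress and spin operator:

    C_hom = Σ_r f_r [ C_r : A_r + W_r ],   (W_r : D) = w_r·t_r − t_r·w_r ,

with the matrix spin balancing the family spins (a pure strain rate is
imposed on the RVE boundary, so the volume-average spin vanishes). At zero
phase stress this reduces to the plain stress-average composition
`Σ f_r C_r : A_r`.

## Collagen fiber model

Within each family the fiber is a planar sinusoidal beam of circular cross
section: centerline `g(s) = h sin(s/ℓ)`, slope `α = (h/ℓ) cos(s/ℓ)` (the
small-slope convention: α is used directly in the cosines), initial
amplitude `h_0 = 0.2 ℓ_0` (S-test) or `0.25 ℓ_0` (P-test), radius
`r_c = 0.04 ℓ_0`, period parameter `ℓ_0 = 50 µm`. The apparent stiffness
along the chord is

    E_c = E_f · I_c⟨cos α⟩ / ( I_c⟨cos²α⟩ + A_c⟨g²⟩ ),

with curvilinear averages taken with the arc-length measure
`dL = √(1+g′²) ds` (a flat-measure variant, with Bessel closed forms
`⟨cos α⟩ = J₀(h/ℓ)`, `⟨cos²α⟩ = (1+J₀(2h/ℓ))/2`, `⟨g²⟩ = h²/2`, is kept as
a cross-check; the two agree within 1% for `h/ℓ ≤ 0.3`). A straight fiber
recovers `E_f = 50 MPa`; at the S-test geometry `E_c/E_f ≈ 0.0195`.

**De-crimping law.** The printed sources do not give the (h, ℓ) evolution
explicitly, so the package adopts a kinematic law: the accumulated
along-the-chord strain `ε` (incremented by `c·d_i·c` each step) stretches
the period affinely, `ℓ = ℓ_0 (1+ε)`, and the amplitude follows from
conservation of the inextensible centerline arc length
(`4ℓ√(1+k²)E(m)` per period, `k = h/ℓ`, `m = k²/(1+k²)`, E the complete
elliptic integral of the second kind). When the chord catches up with the
initial arc length the fiber is fully recruited (`h = 0`, `E_c = E_f`).
This reproduces the monotone stiffening and the recruitment plateau from
quantities the chord-modulus formula defines. The initial chord strain is
zero in the unloaded configuration. For `k_0 = 0.2` full recruitment
occurs at a chord strain of ≈ 1.0%, for `k_0 = 0.3` at ≈ 2.2%; because
the fibers are much stiffer than the matrix even when crimped, their
chord strain lags the tissue strain and recruitment spreads over a finite
stretch range.

## Time stepping and the staggered scheme

A unit pseudo-time step makes all rates increments. Each load increment:

1. solves the weak-form equilibrium with the constitutive tangent frozen
   at step n (see below),
2. per Gauss point, updates the macroscopic stress `T ← T + C_n : D`,
   convects the wall triad with the incremental deformation gradient
   (K follows the deformation, T re-orthogonalized, N = K×T),
3. evaluates the phase fields from the step-n concentration operators,
   updates the phase stresses (Jaumann convection with the phase spins),
   evolves each fiber triad by the normalized explicit update
   `a ← (a + (d_i+w_i)·a)/‖·‖`, accumulates the chord strain, updates the
   crimp geometry and chord modulus,
4. rebuilds the concentration operators and homogenized tangent for the
   next step.

The incremental velocity gradient is taken as `L = ΔF − I` (symmetric
part D, antisymmetric part the macroscopic spin); the RVE is loaded with
D only. By default the macroscopic stress update carries no macroscopic
Jaumann convection (micro-scale convection enters through the tangent);
an optional corotational flag adds the macroscopic-spin convection to the
macroscopic and phase stresses and the fiber triads. It is off by
default: the per-increment rigid-rotation error is second order in the
step size and the studied loadings are nearly irrotational in the
central region.

**Triad orthonormalization.** The three triad vectors, evolved
independently, lose orthogonality secularly (each line rotates at its own
stretching-dependent rate); a non-orthogonal triad corrupts the rotation
of the Eshelby operators. After each update the triad is therefore
re-orthonormalized around the *exact* evolved fiber axis (Gram–Schmidt
for the transverse pair). The transverse gauge is immaterial — every
fiber-frame operator is transversely isotropic about `c`. Drift beyond
1e-3 within a single increment still triggers a warning (it indicates an
over-large load step).

## Finite-element solution

Eight-node hexahedra with full 2×2×2 Gauss quadrature on a structured
mesh of the cylinder (target edge `R_o/12` by default, ≥3 element layers
through the media and ≥2 through the adventitia; all counts overridable
for desk-scale runs). Pressure is integrated over the current inner
surface (follower load). The left end section is fully clamped and the
right end section fully prescribed (purely axial motion), accepting the
end boundary layers that motivate the central-region averaging.

Each increment solves the linearized balance with the frozen tangent by a
modified Newton iteration: the trial stress is linear in the increment
(`T_trial = T_n + C_n : D(ΔU)`, strain measured on the step-start
configuration), and the Jacobian combines the material stiffness, the
initial-stress stiffness *consistent with a geometry-frozen trial stress*
(only the variation of the test-function gradients and the volume
element; verified against finite differences), and the follower-pressure
load stiffness (essential here: at physiological pressures it rivals the
10 kPa matrix modulus). A backtracking line search guards against
overshoot and element inversion; iterations stop when the out-of-balance
force falls below 1e-5 of the load scale (external load or end reactions,
whichever is larger). The constitutive/microstructural update runs once
per increment, after equilibration, preserving the staggered structure.
Linear systems are solved by direct sparse factorization.

Near-incompressibility of the media (`ν_M = 0.49`) is handled with full
integration at the default mesh; no selective-reduced integration is
used. The thick-walled-cylinder verification (internal pressure on an
isotropic single-material wall) matches the Lamé solution within 3% in
the central region at small load.

## Numerical choices and degenerate inputs

* Mandel (not Voigt) 6×6 convention throughout, so concentration-tensor
  products and inversions are plain matrix operations; all tensors are
  stored in the global Cartesian basis with frames as explicit rotations.
* The matrix Poisson ratio is capped at 0.49 (the cylinder Eshelby
  closed forms become ill-conditioned toward 0.5).
* Recruitment inversion `ρ(k) → k` is pre-tabulated on a dense grid
  (k ≤ 2, 4001 points) and evaluated by monotone interpolation for whole
  Gauss-point batches; the scalar API uses Brent root finding.
* Dilute-concentration brackets report ill-conditioning beyond condition
  number 1e12; degenerate fiber triads, element inversions and singular
  systems raise immediately rather than propagate.
* The central-region element selection widens minimally when the L/4
  window falls between element-centroid layers on very coarse meshes, and
  the adventitia is selected with its own window so boundary-layer shifts
  cannot empty the fiber averages.

## Reported quantities

θ¹ is the angle of the main-family fiber axis to the axial direction,
`arccos |c·T| ∈ [0°, 90°]`, averaged over central-region adventitial
Gauss points. The mean relative diameter is the current/initial mean
radius of central-region elements. The tissue axial stress is the
volume-weighted mean axial Cauchy stress over both layers; the axial
tangent stiffness is its finite-difference slope with respect to stretch.
The fiber stress is the along-fiber normal component of the fiber-phase
Cauchy stress of the main ±θ¹ pair. The axial–circumferential shear
stiffness is the (K,T)-shear diagonal component of the homogenized
adventitial tangent expressed in the local wall frame.

## Problem sizes

The default mesh (`R_o/12`) is appropriate for production runs; the
shipped case studies, tests and the acceptance script use coarsened
meshes (10×6×4 elements for the acceptance runs, 8×4×3 for smoke tests)
with the standard load steps `ΔP = 5 mmHg`, `Δλ = 0.03` unless a study
prescribes halved steps. At these coarse sizes the clamped-end boundary
layers occupy a substantial part of the segment, so absolute
central-region outputs carry a visible mesh dependence (several percent
between the smoke and acceptance meshes for the P-test diameter); the
qualitative orderings and fold changes are stable across them. The
load-step sensitivity of the final P-test radius is ~0.8% at the smoke
scale and ~2% at the acceptance scale, where the re-inflation passes
near an almost-singular state of the heavily stressed nonsymmetric
tangent and the damped equilibrium iteration accepts ~1e-3 residuals.

## What the tests show — and what they do not

The suite verifies the micromechanical operators against closed forms and
independent bookkeeping (Eshelby components, Voigt-route concentration,
Bessel-form averages, quadrature oracles), the FE machinery against exact
Jacobian finite differences, the Lamé solution and a single-element
material-point equivalence, and the qualitative physiology of the
protocols (reorientation toward the axis under stretch, suppression of
reorientation by pressure, shear stiffening under both stretch and
inflation). The synthetic study conditions are the printed parameter sets
of the two test columns; no real imaging or force data enters the
pipeline, so agreement with the tests does not by itself demonstrate
predictive accuracy on real vessels — parameters there must come from
histology, and the media's microstructure, damage, viscoelasticity and
residual stresses are outside the model.

## Known limitations

* The hypoelastic formulation is path-dependent and not exactly
  objective between increments (by construction of the explicit scheme);
  step-size control is the only error control.
* Aligned, recruited fibers are forced to follow the axial tissue
  stretch (the along-axis strain concentration of an infinite cylinder
  is exactly 1), so near-axial families accumulate large chord strains
  and stresses at λ = 1.6–1.8; there is no fiber damage or unfolding
  beyond de-crimping to relieve them.
* Discrete fiber families only (no orientation distributions); media
  homogeneous; no residual stress/opening angle; no contact or dynamics.
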