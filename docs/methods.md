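# Methods

## Physical model and assumptions

The cytoplasm of an isolated, substrate-attached epithelial cell is treated
as an incompressible Newtonian fluid at zero Reynolds number in steady
state. Activity enters through a prescribed orientational field
**p** = S(ρ,z) **e**_φ: actomyosin bundles are azimuthally aligned (no
vertical tilt of the bundles themselves) and their local density/order is
the scalar S ∈ [0,1]. Two active stresses act: a contractile force dipole
along the bundle axis (coefficient ζᵃ) and a torque dipole from bipolar
myosin motors walking on antiparallel filaments (coefficient ζᶜ). The
internal spin degree of freedom is eliminated in the molecular-scale limit,
leaving a body-force form of the momentum balance. Non-dimensionalising
lengths by the cell radius R₀, velocities by ζᵃR₀/η and pressure by ζᵃ
leaves one control parameter, the chirality ratio ζ = ζᶜ/(ζᵃR₀).

In axisymmetric cylindrical coordinates the system splits:

* an azimuthal scalar problem, (∇² − 1/ρ²)v_φ = (ζ/ρ) S ∂_z S, linear in ζ
  and forced only where S varies with height;
* a meridional Stokes problem for (v_ρ, v_z, P) forced by S²/ρ,
  independent of ζ.

Consequences used as tests: v_φ scales linearly with ζ and vanishes for
ζ = 0 or z-independent S; flipping the sign of ζ mirrors the rotation and
leaves the meridional circulation untouched.

The model contains no nucleus or other organelle, no boundary motion, no
inertia, and no feedback of flow on the actomyosin pattern (S is fixed).

## Geometry

The dorsal boundary is three tangent pieces: an apical cap circle (radius
r₁) centred on the axis, a shoulder circle, and a straight wedge meeting
the substrate at radius R₀ with contact angle α. The shoulder circle
(radius r₂, centre (ρ₂, Z₂)) is fixed by two tangency conditions — distance
r₂ from the wedge line, external tangency to the cap — which reduce to a
quadratic for Z₂ solved in closed form; junction radii ρ₁, ρ₃ follow. The
closed forms are verified against a root-finder solving the raw tangency
system (agreement to 1e-8 relative on the reference set and 20 randomly
perturbed sets), and the assembled boundary is C0/C1 at both junctions by
construction. Reference values: Z₀ = 8.2 µm, R₀ = 35 µm, r₁ = 15 µm,
ρ₂ = 22 µm, α = 7°. The degenerate limit α → 0 (the Z₂ denominator sin²α)
is rejected rather than regularised; it is never needed.

## Activity field

S is a product of smoothed steps: a sharp tanh across the band inner edge
(sharpness λ₁ = 150/R₀ µm⁻¹, inward offset ξ = 0.06 R₀) and a soft radial
cutoff (λ₂ = 20/R₀ µm⁻¹ at ξ₃ = 0.7 R₀), in a slab tilted by β = 1.7 α.
Near the apex the inner edge follows a circle concentric with a "tilted
shoulder" obtained from the same tangency construction with (β, Z₀′ = 1.5
Z₀) in place of (α, Z₀). The two formulas are tangent along a dividing line
through their common tangency point; the circular branch is applied on the
apex side of that line and the straight branch on the cell-edge side, which
carves the central hole of the ring (apical dome free of actomyosin, ring
inner radius ρ_a ≈ 14 µm where S first reaches 0.8). Branch mismatch along
the dividing line is checked numerically (max |ΔS| ≈ 4×10⁻⁴, far below any
tolerance that matters). Where printed unit annotations of these parameters
are inconsistent, the only dimensionally consistent reading is used:
lengths in µm, sharpness in µm⁻¹. The unsubscripted sharpness of the
circular branch is taken equal to λ₁ (same inner-edge role) and is
overridable (`lambda_cap_per_um`).

The solver needs S ∂_z S; ∂_z S is coded analytically per branch and
verified against central differences (relative 1e-5).

## Discretisation

Structured boundary-fitted triangulation of the meridional cross-section:
radial columns at uniform ρ, nodes uniformly spaced in z up to the exact
dorsal curve, and a single collapsed node at the contact line where the
height vanishes (fan of triangles). All boundary vertices lie exactly on
the boundary; edges are straight (geometric error O(h²)). Default target
edge length h = 0.35 µm (R₀/100), resolving the λ₂ cutoff layer (~1.75 µm)
with ≥ 5 elements and the sharp λ₁ inner edge (~0.7 µm transition) with ~2;
a refinement study (below) shows this suffices for the reported
observables.

Taylor–Hood elements: continuous P2 for each velocity component, P1 for
pressure (inf-sup stable). All weak forms carry the axisymmetric ρ weight,
which regularises the 1/ρ and 1/ρ² terms; quadrature points are interior,
so no special axis treatment is needed. Quadrature is a degree-9 collapsed
Gauss–Jacobi product rule built in code (no tabulated constants); a
closed-form degree-5 rule is available. Boundary conditions: essential
v = 0 on the ventral boundary; essential v_ρ = v_φ = 0 on the axis with
v_z natural there; dorsal free slip as v·n = 0 via a boundary penalty
(weight 10⁸, measured penetration ≤ 10⁻³ of the peak speed) with the
tangential pseudo-traction and the azimuthal flux natural. For v_φ the
ρ-weighted natural condition is equivalent to a vanishing normal
derivative, so the two common readings of "free slip" coincide here.
Pressure is gauged to zero ρ-weighted mean by a scalar Lagrange multiplier.
The saddle system is solved with a deterministic direct sparse
factorisation; the discrete (pressure-tested) divergence residual is
~10⁻¹⁰ relative and each accepted solve enforces it below 10× the
configured tolerance. Note that only this weak divergence is small:
the pointwise divergence of a Taylor–Hood velocity field is O(h²), as for
any such discretisation.

### Verification

Method of manufactured solutions on an exactly meshed rectangle (so element
order is not masked by boundary approximation): stream-function targets
satisfying continuity identically, body forces derived symbolically,
inhomogeneous Dirichlet data on the walls. Observed L2 orders ≈ 3.5 for
velocities (theoretical 3 for P2) and ≈ 2.5 for pressure (theoretical 2).
Mesh refinement on the cell domain: peak |ṽ_φ| changes < 0.1% from h to
h/2; the calibrated profile peak changes ~1%.

## Observables

* **z-averaged angular velocity**: per radial grid point, the plain mean of
  −v_φ/ρ over z uniformly sampled between substrate and dorsal surface
  (per-column average, no volume weighting); clockwise viewed from above is
  positive everywhere in the package. Radii below one grid step use the
  axis limit −∂_ρ v_φ.
* **ring inner radius ρ_a**: leftmost radius whose column-maximum of S
  reaches 0.8, bisection-refined to 1e-3 µm. Reducing over the column
  maximum makes the measure independent of an arbitrary z-slice choice.
* **profile peak**: parabolic interpolation through the discrete maximum;
  location reported as ρ_peak/ρ_a; boundary maxima are flagged instead of
  interpolated.
* **calibration**: velocity scale = (measured peak speed)/(simulated peak
  dimensionless speed); time scale = R₀/velocity scale; ω converts to
  deg/hr by dividing by the time scale. The measured peak speed defaults to
  10⁻² µm/s, the upper end of the observed 5×10⁻³–10⁻² µm/s range and the
  only value consistent with a ~50 µm/s velocity scale at a 2×10⁻⁴
  simulated peak.
* **surface swirl**: mean (v_ρ, v_φ) in a layer at 8% fractional height
  from the chosen surface. Radial sense = sign of mean v_ρ; rotation sense
  = sign of mean v_φ; spiral handedness from their combination (streamlines
  obey dφ/dρ = v_φ/(ρ v_ρ): equal signs wind sinistrally, opposite signs
  dextrally) — the sign of v_φ alone cannot distinguish the dorsal and
  ventral patterns, which share the clockwise rotation. Means below a noise
  floor give "indeterminate".

## Planar (PIV-style) pipeline

Operates in image coordinates (y down), center supplied by the user (in the
experiments: the xy position of the cell's highest point). Decomposition
v_φ = x̂v_y − ŷv_x, v_r = x̂v_x + ŷv_y, ω = v_φ/r; with y down, positive v_φ
is clockwise on screen, matching the clockwise-positive reporting
convention. Points within one grid spacing of the centre (configurable) are
excluded from ω to avoid the 1/r blow-up — the data's handling of small
radii is not documented, so this choice is explicit and conservative.
Temporal averaging precedes angular averaging (per-radius-bin mean and
SEM = sd/√n), matching the order used on the experimental data; default bin
width is one grid spacing. The radius axis may be rescaled by a per-cell,
manually identified ring inner radius.

## Nuclear rotation

Orientation of the line joining two tracked nucleoli via atan2 in image
coordinates; frame-to-frame increments wrapped into (−180°, 180°] (vector
mode, default — the nucleoli are individually identified) or (−90°, 90°]
(line mode, label-swap robust) and summed, so full turns accumulate.
Windowed mean angular velocity is the endpoint slope with linear
interpolation at the window edges; the window is always explicit because
the relevant start time differs between experiments. Invariants tested:
label-swap and translation invariance, time-reversal antisymmetry,
smoothness across wrap crossings.

## Synthetic data

The generators emulate the *statistical structure the pipeline assumes*,
not microscopy: swirl fields are steady rotation Ω(r) (clockwise-positive,
default 50 deg/hr) plus radial flow v_r(r) (default −0.002 µm/s) on a
masked circular 1 µm grid, with i.i.d. per-component Gaussian noise of 10%
of the local speed per frame; landmark tracks are rigid pairs with
per-frame angular jitter and centre drift. All generators are
seed-deterministic. What passing tests show: the pipeline recovers known
rotation/inflow unbiasedly under Gaussian velocity noise. What they do not
show: robustness to PIV-specific artefacts (spatially correlated errors,
outlier vectors, mask erosion, peak locking), which are upstream of this
package's scope.

`sample_solution_to_grid` bridges simulation and planar pipeline by
evaluating (v_ρ, v_φ) on a chosen layer (dorsal/ventral offset or
max-speed height per column) and composing image-convention components with
v_φ(screen) = −v_φ(model), so a clockwise model flow appears clockwise on
screen.

## Numerical choices and degenerate inputs

Direct solver only (deterministic reports); penalty 10⁸ balances
penetration error against conditioning; ρ_a bisection tolerance 1e-3 µm;
profile grids 240 radial × 60 vertical samples (doubling changes the peak
< 3%). Rejected inputs raise informative errors: tangency radicals < 0,
sin α or sin β < 1e-8, mesh size outside (0, R₀/10], centres outside the
grid, coincident landmarks (dropped; > 5 consecutive → error), windows
outside the trace support.

## Problem sizes

Default runs use the 0.35 µm mesh (≈ 9.8k velocity nodes per component,
≈ 4.8k triangles; ~3 s per full solve), 40-frame synthetic series on a
61×61 grid, and 100-seed Monte-Carlo checks — sizes chosen so the full
verification suite and the reproduction script run in minutes on one CPU
while leaving the reported observables mesh-converged (refinement study
above).

## Known limitations

* The activity pattern is prescribed, not emergent; questions about ring
  formation are outside the model.
* Free slip is imposed on the polygonal approximation of the dorsal curve;
  the O(h) normal error is invisible at the reported tolerances but would
  matter for higher-order studies (isoparametric elements would fix it).
* The contact-line wedge (7°) carries a stress singularity where no-slip
  meets free slip; velocities there are ~0 and the reported observables are
  insensitive to it, but local fields near ρ = R₀ should not be
  over-interpreted.
* The calibrated deg/hr values inherit the uncertainty of the measured peak
  speed (factor ~2 across the reported range); ratios and locations
  (ρ_peak/ρ_a) do not.
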