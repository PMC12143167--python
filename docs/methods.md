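# Methods

## Model

The tumor is three concentric regions on a disc of radius R_ht = 2 cm:
necrotic core (r < R_nt = 0.5 cm), viable rim (R_nt ≤ r < R_vt = 1 cm)
and healthy tissue (r ≥ R_vt).  Interstitial flow is Darcy flow in a
porous medium whose mass balance carries a Starling transvascular
source φ_VS (viable and healthy regions) and a lymphatic sink φ_LS
(healthy only); the necrotic core has neither.  Eliminating the
velocity gives, per region,

    ∇²P_IS = β² (P_IS − P_SS),   β² = (L_p·S/V + L_PL·S_L/V)/K,

with β = 0 in the core.  P_SS is the conductance-weighted average of
the effective pressure P_EF = P_V − σ_s(π_V − π_IS) and the lymphatic
hydrostatic pressure P_L; the dimensionless resistance α = R·β is
reported with reference length R = R_vt = 1 cm, giving α = 36.8 / 29.3
/ 17.19 for the 0/50/100 % vascular-normalization viable rims.

Solute transport is a transient convection–diffusion–reaction equation
for the interstitial concentration C_IS, with

* hindered diffusivity D_EF = (2ξ/(3−ξ))·D_DIS, D_DIS from
  Stokes–Einstein (k_B T / 6πμn_r, SI, converted to cm²/s);
* transvascular extraction −P·(S/V)·Pe/(e^Pe−1)·C_IS with
  Pe = φ_VS(1−σ_rc)/(P·S/V), valid under the negligible-plasma
  hypothesis C_PL = 0 (intratumoral injection, slow leak-back);
* lymphatic loss φ_LS·C_IS (healthy region) and first-order
  degradation τ_deg·C_IS (nano–bio interactions, macrophage uptake).

## Interface conditions — a deliberate choice

The pressure equation above is the strong form *after dividing by K*
region-wise.  Its natural weak form enforces continuity of P and of
∇P at the internal interfaces, which is the formulation this package
discretizes and which its closed-form radial solution matches by
default.  The physically conservative alternative — continuity of the
Darcy flux K∇P — is available in both solvers (`k_weighted=True` /
`flux_weighted=True`).  The two differ visibly only in the shape of the
pressure drop across the viable–healthy interface where K jumps by a
factor ≈ 4.8; the region plateaus (the headline pressures) are
identical because they are set by the equilibria P_SS, not by the
interface matching.  Consequently the default (gradient-continuity)
solution conserves the conductivity-scaled exchange ∫(φ_VS − φ_LS)/K dΩ
exactly, while the conservative option balances ∫φ_VS dΩ against
∫φ_LS dΩ to machine precision; the tests check each formulation against
its own conservation law.

## Closed-form radial solution

Under radial symmetry each region's homogeneous solutions are known:
I₀/K₀(βr) for the plane-disc problem (ν = 1, the geometry the 2D FEM
actually solves) and e^{±βr}/r for the sphere (ν = 2, the physical
narrative); the avascular core reduces to a constant by regularity.
Basis functions are normalized at each shell's own radii (scaled
Bessel functions `ive`/`kve`, shifted exponentials) so that matrix
entries stay O(1) up to βr of several hundred.  Matching P and the
(optionally weighted) gradient at both interfaces plus regularity and
the outer zero-flux condition yields a 5×5 dense system.  The solver is
verified against an independent interface-aware finite-difference
discretization (one-sided second-order matching at the interfaces,
Richardson-extrapolated) to 1e-6 relative L∞ on 20 randomized
physiological parameter sets.

The critical necrotic radius R_CN is operationalized as the largest
R_nt (grid 0.05 … R_vt − 0.01 cm, step 0.01 cm) whose center pressure
still reaches (1 − ε)·P_EF,viable with ε = 0.01; the study gives no
formula, only the approximate value ≈ 0.9 cm, which this criterion
reproduces (0.87 cm on the sweep grid, spherical symmetry).  For low
resistance (α ≈ 5) the plateau never reaches 99 % of P_EF at any core
size, so the sweep returns the smallest grid value with a warning flag;
the qualitative ordering (smaller R_CN at smaller α) is preserved.

## Discretization

*Mesh.*  Deterministic structured polar ("spiderweb") triangulation:
rings track the requested maximum edge length h, the two interface
circles and the outer boundary are rings, per-ring node counts grow
with circumference, and consecutive rings are stitched by an angular
merge.  Minimum interior angles are ≈ 30° at all ladder resolutions.
Quadratic (6-node) elements are isoparametric: mid-edge nodes of edges
lying on one of the three circles are snapped onto the circle, so the
curved interfaces are represented to quadratic geometric order — this
is what allows the observed L² convergence of order ≈ 2.9 for P2
(≈ 1.9 for P1) on the finest ladder rungs; with straight edges the
geometric error would cap both at second order.  The refinement ladder
is h ∈ {0.2, 0.1, 0.05, 0.03, 0.01} cm with the working mesh at 0.03 cm
(case 4); element counts are generator-specific and are not contractual.

*Flow.*  Standard Galerkin: stiffness ∫∇P·∇u + reaction ∫β²Pu with
region-wise constants, Gaussian quadrature exact for the element order
(3-point for P1, 7-point degree-5 for P2), sparse direct solve.  The
pure-Neumann problem is definite without pinning because β² > 0 outside
the core (asserted via the smallest eigenvalue in tests).  Velocity is
recovered by consistent-mass L² projection of −K∇P.  An optional radial
weight |x| in all integrands converts the disc problem into the
spherically symmetric one (validated against the ν = 2 closed form).

*Transport.*  Same element machinery; convection is the
non-conservative v·∇C with the divergence of the projected velocity
folded into the reaction coefficient, so the pair reproduces ∇·(vC);
an `analytic_reaction` mode substitutes the continuum-equal φ_VS − φ_LS
as a consistency check (agrees to < 1 % at the test resolution).  Time
integration is backward Euler (default) or Crank–Nicolson with fixed
step; the constant system matrix is factorized once.  No convection
stabilization is applied by default — at the µm/s Darcy velocities and
1e-7 cm²/s diffusivities of this problem, element Peclet numbers are
far below one; a streamline-diffusion switch exists for stress tests.
The per-step mass ledger accumulates each loss channel with the same
θ-weighting as the scheme, so mass + Σlosses = initial mass holds to
roundoff by construction and any closure defect indicates an assembly
error.

*Tolerances.*  Linear solves are direct; convergence is declared at
residual ≤ 1e-4 (absolute 1e-6, relative 1e-3).  The Patlak factor
Pe/(e^Pe−1) switches to a three-term Bernoulli series below |Pe| = 1e-6
and to Pe·e^{−Pe} above Pe = 45 to avoid 0/0 and overflow.

## Parameter conventions

* Units: cm–s–mmHg internally; 1 mmHg = 133.322 Pa for reporting only.
* Healthy-region vascular permeability is read literally as
  0.73×10⁻⁹ cm/s.
* "Absence of functional lymphatic dynamics" means P_L = 0 with the
  sink retained; the functional case applies P_L = −4 mmHg.  A separate
  switch can zero the lymphatic conductance entirely (not a study case).
* Vascular normalization replaces the viable rim's K, L_p, S/V, σ_s;
  at 100 % they equal healthy-tissue values.
* Nanoparticle "size" labels are diameters; the Stokes–Einstein radius
  is size/2.
* Injection: uniform C₀ over the necrotic core (4 mg/cc default,
  100 mg/cc for the carrier comparison), nodes on the interface taking
  the inside value.  The dose statement ("4 mg/cc dissolved in 0.1 ml")
  does not uniquely fix the initial field; the uniform-core convention
  follows the study's initial-condition figures.
* Resistance sweeps (α targets below the baseline 36.8) are realized by
  scaling K globally in all three regions by (α_base/α_target)², one
  consistent reading among several the study leaves open; those swept
  values are reported but not treated as quantitative targets.
* The degradation-sensitivity grid defaults to τ_deg ∈
  {5.8e-4, 5.8e-6, 5.8e-8} s⁻¹ around the baseline 5.8e-6 s⁻¹
  (the study does not print its three grid values); it is configurable.

## Problem sizes used by tests and the acceptance script

Flow solves for the headline pressures use quadratic elements at
h = 0.05 cm (≈ 20k nodes; the plateau is mesh-insensitive well before
that).  Convergence is measured on the two finest ladder rungs
(h = 0.03, 0.01).  Transport tests and property checks run quadratic
elements at h = 0.1 cm with Δt = 300 s over 24 h — a scaled-down
version of the working discretization (h = 0.03, Δt = 60 s, 72 h) that
preserves every qualitative finding: plateau values, carrier ordering,
size monotonicity and ledger closure.

## What the synthetic scenarios do and do not show

There is no external data: geometry, physiology and doses are the
tabulated study conditions, and the generator builds meshes and
configurations from them deterministically.  Passing tests therefore
demonstrate the solvers' internal correctness (closed form vs FEM vs
independent finite differences, conservation, convergence order) and
the reproduction of the study's printed numbers under its idealized
assumptions — homogeneous per-region vasculature, static geometry,
radially symmetric tumor, constant degradation rate, C_PL = 0.  They do
not validate the model against heterogeneous real tumors, dynamic
vasculature/angiogenesis, particle–matrix surface interactions, bound/
free drug kinetics or plasma pharmacokinetics, all of which are outside
the model class.

## Known limitations

* The spec of velocity magnitudes is scale-ambiguous in the source
  material; only velocity peak locations and orderings are asserted,
  never magnitudes (Darcy recovery from the tabulated parameters gives
  µm/s-scale speeds).
* The gradient-continuity default sacrifices exact physical flux
  balance across the K jump (see Interface conditions); use
  `k_weighted=True` where conservation across regions matters.
* Nodal concentrations can undershoot slightly (no discrete maximum
  principle) at the sharp injection front; the effect is < 0.1 % of the
  injected mass at test resolutions.
* The structured polar mesh is specific to concentric-circle geometry;
  irregular or image-derived geometries are out of scope.
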