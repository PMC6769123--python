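# Methods

This note documents the model equations, the discretization, the parameter
choices with their provenance, the synthetic study geometries, and the
numerical decisions that were genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Governing equations

Two primary nodal fields on the reference configuration Ω₀: displacement
u(X,t) [mm] and transmembrane potential Φ(X,t) [mV].

* Mechanics (quasi-static): 0 = Div(F S) + body force, with
  S = S_pas(C) + S_act. Inertia is neglected — the loading and activation
  time scales (ms–tens of ms) are slow compared with elastic wave transit
  across the mm-scale specimens.
* Monodomain potential: Φ̇ = Div(D ∇Φ) + (k_φ/k_t)(f_e + f_m), material
  form; the conductivity D = J d_iso C⁻¹ + J d_ani f₀⊗f₀/λ² carries the
  deformation dependence, zero-flux boundaries throughout.

Kinematics, invariants and the three passive energies (TIC, TII, HO) are
described in `cardioemx.constitutive`; all stresses are second
Piola–Kirchhoff (S = 2∂Ψ/∂C) with fully analytic consistent tangents,
assembled from scalar derivatives with respect to the invariant basis
(I₁, I₄f, I₄s, I₈fs, J). The tension switch ϑ is a sharp Heaviside in the
respective stretch, strictly active for λ > 1 — value *and* tangent use the
same strict branch, so the reference state keeps the isotropic
linear-elastic tangent.

## Time discretization and solver

Backward Euler for Φ̇ and for both internal variables: the recovery
variable r (closed-form root of the quadratic implicit update, with
consistent sensitivity dr/dφ) and the active tension T (linear implicit
update, sensitivity dT/dΦ including the rate-switch derivative). Internal
variables live at quadrature points and are re-updated inside every Newton
iteration from the step-start values, so the monolithic Jacobian — all
four blocks ∂R_u/∂u, ∂R_u/∂Φ, ∂R_Φ/∂Φ, ∂R_Φ/∂u — is exact where the
energy is smooth. The sparse system is solved directly (SuperLU).

Newton controls worth knowing about:

* absolute residual tolerances (1e-5 mN / 1e-5 in potential-equation
  units) — tiny against the mN-to-N scale of the benchmark forces;
* the sharp switches make the *tangent* discontinuous at λ = 1 (stress and
  current are continuous), so Newton can cycle between switch branches
  with a small bounded residual instead of converging. A stalled best
  iterate below 1e-2 mN / 1e-3 is accepted; a vanishing update
  (<1e-9 mm/mV) is likewise accepted. Otherwise the step is halved and
  retried (≤5 levels).
* quadrature: 2×2×2 Gauss for hex8; a degree-2 4-point rule for tet4
  (the deformation gradient of a linear tet is constant, so mechanics is
  unchanged versus 1-point integration; the extra points integrate the
  potential mass term exactly).
* near-incompressibility on coarse meshes: the volumetric penalty
  κ(J−1)², κ = 10⁴ kPa, is optionally integrated on the element-center
  point only (`SolverConfig.mean_dilatation`, hex8). Pure-displacement
  linear tets with this penalty emit a locking warning.

## Parameters and provenance

Global units are mm / ms / kPa / mV; the derived force unit is mN.

Electrophysiology (Aliev–Panfilov, canonical constants): α = 0.01, c = 8,
b = 0.15, γ = 0.002, μ₁ = 0.2, μ₂ = 0.3; scaling k_φ = 100 mV,
δ_φ = 80 mV (so φ = 0 is −80 mV and φ = 0.6 is −20 mV), k_t = 12.9 ms.
Conduction: d_iso = 1.0 / d_ani = 0.1 mm²/ms on the large plate,
d_iso = 0.1 / d_ani = 0.3 on the small plate and the ventricle. MEF:
reversal φ_s = 0.6; G_s is the study variable (15 in the plate benchmark).

Active stress: k_T = 0.49 kPa/mV, Φ_r = −80 mV (saturated tension 49 kPa,
close to the ~45 kPa measured in rat); rate switch ε(Φ) with
ε₀ = 0.1 ms⁻¹ (relaxation), ε∞ = 1 ms⁻¹ (development), ξ = 1 mV⁻¹ about
Φ̄ = 0 mV.

Passive laws. The HO constants are the standard porcine simple-shear fit
halved for rat tissue (a = 0.248, b = 7.209, a_f = 7.597, b_f = 20.417,
a_s = 1.642, b_s = 11.176, a_fs = 0.331, b_fs = 9.466; κ = 10⁴ kPa). For
the polynomial laws no equally canonical fit exists, and parameters at the
raw shear-fit scale (a few kPa) are crushed by the 49 kPa active tension
into nonphysical states (J → 1e-3). The defaults are therefore *effective
organ-scale stiffnesses*, calibrated once at a material point so that free
(isotonic) contraction against the saturated tension settles at the same
bounded shortening as the exponential law: TIC Λ = 100, μ = 40, η = 60 kPa
(λ_free ≈ 0.54, with a visible volume dip), TII μ = 50, η = 60 kPa
(λ_free ≈ 0.69); HO's exponential self-limits at λ_free ≈ 0.65. This
calibration targets the deformation magnitude scale only; no benchmark
time or sweep metric entered it.

## Study geometries (all generated in code)

* Plates: structured hex8 grids, fibers along x, sheets along y. Large:
  100×100×12 mm, 21×21×2 bricks; small: the same topology scaled to
  10×10×1.2 mm. Mid-plane boundary edges fixed in z, two corner pins
  remove the remaining rigid modes. The triangular load pulse (peak at
  5 ms, zero at 10 ms) acts in +z on every node of the central
  parallelepiped (20% of the in-plane extent, full thickness); the pulse
  amplitude is *per node* — 300 mN (0.3 N) on the large plate, area-scaled
  to 3 mN on the small one. A total-force reading of the protocol was
  tried first and produces stretches of only ~4%, too weak to ignite any
  wave; the per-node reading reproduces the described self-excitation.
* Cube: unit hex cube, free boundaries with 3-2-1 pinning, uniform
  activation prescribed from the space-clamped cell trace — the isotonic
  volume-ratio experiment.
* Left ventricle: a *synthetic* truncated-ellipsoid shell at rat scale
  (endo semi-axes 2.5/4.5 mm, epi 4.25/6.25 mm, base plane z = 0). The
  reference geometry of interest is MRI-derived and not reproducible, so
  organ-specific numbers are out of reach by construction; the synthetic
  stand-in keeps wall thickness, cavity size and the rule-based fiber
  field: helix angle linear in normalized wall depth from +80°
  (endocardium) to −70° (epicardium) about the transmural axis, sheet
  direction transmural (the standard rule-based choice; the source data
  does not constrain it). The structured (θ, v, w) grid collapses to a
  pole line at the apex; cells are either kept as (collapsed) hex8 or
  split into tetrahedra with a parity-alternating 5-tet pattern (even
  circumferential count ⇒ conforming faces; degenerate pole sub-tets are
  dropped).

## LV sweep conditions

The feedback study runs models × conductances on one coarse hex8 LV mesh
(target size 1.5 mm → 14×5×2 cells, 213 nodes) with the volumetric term on
reduced quadrature: at κ = 10⁴ kPa a coarse pure-displacement mesh locks
badly, and the hex8-with-reduced-volumetric formulation is the cheapest
locking-safe choice at this size (the tet4 variant remains available and
tested). Base ring fixed, seven contiguous basal endocardial nodes held at
−20 mV for 40 ms, apex probe on the epicardial pole. Runs last 600 ms with
dt = 1 ms: with k_t = 12.9 ms the cell model's action potential lasts
≈400 ms, so the late state ("peak 2" / residual) is read once the
feedback-free references have returned to within ~0.1 mV of rest.
Residual metrics are means over the final 150 ms; Δ-metrics are absolute
differences against the same model's G_s = 0 run. The window is longer
than it may look: strong stretch feedback can leave the ventricle not in
a stationary residual state but in an *oscillatory* one (stretch-induced
auto-rhythmicity — here the exponential law at G_s = 10 cycles with a
~100 ms period, while G_s = 50 reaches a stationary non-relaxed
equilibrium), and a window shorter than one period would turn the
"plateau level" into a phase-dependent snapshot. Averaging over ≥1 period
yields the cycle mean and leaves stationary states unaffected.

What the synthetic setup does and does not show: it reproduces the
*mechanisms* — compressible TIC develops almost no fiber stretch (feedback
stays off), incompressibility plus transmural fiber rotation stretch the
midwall of TII/HO (feedback on), conduction speeds up with G_s, residual
metrics grow with G_s and are strongest for the exponential law. Absolute
millivolt/millimeter values depend on the real ventricular geometry and
are not comparable.

## Numerical choices and limitations

* dt defaults: 0.5 ms (plates; upstroke resolution), 1.0 ms (LV, cube).
* The depolarization-completion time is the linearly interpolated crossing
  of min-over-nodes Φ through 0 mV.
* Mesh consistency is exercised on a reduced wave problem (a quarter-scale
  plate) so that two refinement levels fit in a unit-test budget; the
  benchmark meshes themselves are fixed by the protocol.
* Known limitations: no chamber pressure, Purkinje system or right
  ventricle; phenomenological kinetics (no biophysical ionic currents); no
  length-dependence of active tension (Frank–Starling), which makes free
  contraction stronger than physiological; dead (non-follower) nodal
  loads; the fixed base exaggerates basal stresses. These mirror the scope
  of the modeling framework this package implements.
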