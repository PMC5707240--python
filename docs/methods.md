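# Methods

This note records the model equations as implemented, the numerical
choices, the closures that had to be decided, and what the shipped test
conditions do and do not establish.

## Kinematics

Prolate spheroidal coordinates (μ, ν, φ), interfocal half-distance *a*:
x = a sinh μ sin ν cos φ, y = a sinh μ sin ν sin φ, z = a cosh μ cos ν.
The reference wall is μ_in0 ≤ μ0 ≤ μ_out0, ν_up ≤ ν0 ≤ π with a = a₀.
The deformation family keeps ν = ν₀, sets a = a₀ + a₁,
φ = φ₀ + a₃(cos ν₀ − cos ν_up), and defines μ(μ₀, ν₀) implicitly by a cubic
in cosh μ whose coefficients are linear in a₂; the relation is constructed
so that |J| dμ dν dφ is pointwise invariant, hence det F = 1 exactly (the
implementation achieves ≤ 1e−12 on quadrature grids).

*Root solve.* The cubic h(c) = c³/3 − c cos²ν₀ is strictly increasing for
c = cosh μ ≥ 1, so the physical branch (continuous with c = cosh μ₀ at zero
deformation) is unique.  A safeguarded vectorised Newton iteration with
warm starts from the previous time step converges to 1e−14 relative in 2–4
iterations; states for which no root with μ > 0 exists raise a
domain-exit error.  ∂μ/∂μ₀ and ∂μ/∂ν₀ follow by implicit differentiation.

*Strain derivatives.* ∂E/∂a₃ is analytic (a₃ enters one component of F,
linearly).  ∂E/∂a₁ and ∂E/∂a₂ use central differences with step 1e−5,
re-solving the cached mapping; the tests validate them against
Richardson-extrapolated differences to 1e−6 relative.  A finite-difference
path was shipped instead of fully symbolic derivatives because the chain
through the implicit mapping is error-prone to hand-derive and the
difference scheme is exact to O(h²) with h far above roundoff.

## Fiber architecture

Fibers lie in μ₀ = const surfaces with φ₀ = φ_b + ω(cos ν₀ − cos ν_up).
The equatorial helix angle interpolates linearly in μ₀ between ψ_in = 85°
(endocardium) and ψ_out = −65° (epicardium); the quadrant-adjusted angle
ψ* ∈ [0, π) makes the fiber *line* field continuous where ψ changes sign
(the direction flips f → −f there; only f ⊗ f enters the stress).  The
wrapping parameter ω = cot ψ*_eq coth μ₀ is evaluated per μ₀ at the equator
and reused at all ν₀.  Where ψ_eq = 0 exactly the fibers are treated as
circumferential (stretch = circumference ratio); the default quadrature
grids do not contain that surface.  Fiber stretch is computed both from the
arc-length ratio of the deformed fiber paths and from λ_f² = f₀·C f₀; the
two agree to roundoff and both are asserted in the tests.  Sarcomere length
is L_s = λ_f L_s0 with L_s0 = 1.82 μm uniform in the reference state.

## Constitutive laws (defaults in parentheses, all overridable)

* Active: σ_ff = A G (F₀ + k_av dε_f/dt)(1 + k ε_f,ed);
  F₀ = 300 kPa, k_av = 0.5 kPa·s (interpreted as kPa·s so the
  force–velocity term carries kPa; no unit is stated for it anywhere),
  k = 0 (preload force scaling off), k′ = 1 (preload still broadens the
  activation wave through d = 1/(1 + k′ε_f,ed)), L_smax = 2.23 μm,
  L_sw = 0.2 μm, T_a = 0.4 s, T_c = 1 s.  A(t) = [sin(π t/T_a)]^d on
  [0, T_a], else 0; end-diastolic strain is snapshotted per material point
  at each cycle start (activation onset), the first cycle using the
  reference state.  Negative σ_ff under extreme shortening is not clamped
  by default (a config flag exists) — none occurred in the shipped runs.
* Passive: Ψ = c₁(e^W − 1)/2 in the fiber frame, W quadratic with
  b_ff = 5, b_xx = 3, b_fx = 7, c₁ = 1 kPa; S_e = ∂Ψ/∂E (asserted against
  numerical gradients).  W > 250 raises a diagnostic overflow error.
* Viscous: S_v = k_vm C⁻¹ Ċ C⁻¹ with k_vm = 0.025 kPa·s — the exact
  pull-back of the Newtonian form k_vm(∇v + ∇vᵀ) under det F = 1.
* The incompressibility reaction stress does no work in this
  volume-preserving family and is omitted from the balance; reported
  stress fields are deviatoric Cauchy components, where it cancels anyway.

## Weak-form balance and the basal closure

Contracting the virtual-work statement with ∂E/∂a_i gives three equations
M(a, t) ȧ = b(a) p − g(a, t); the rate linearity comes from S_v and the
force–velocity term, and M is symmetric positive definite whenever
k_vm > 0.  Internal integrals use 2-D composite Simpson quadrature on a
9 × 11 (μ₀ × ν₀) grid (17 × 21 shifts converged stroke work by < 1%).

The external coefficients b_i combine the endocardial pressure line
integral with a basal term modelled as the cavity pressure acting on the
flat basal closure disk translating axially with the basal endocardial
edge.  Integration by parts of the endocardial swept-volume integral shows
this combination equals ∂V/∂a_i *exactly* (the boundary term of the parts
integration is precisely the disk term), so external work equals p dV/dt
and net internal work equals stroke work for every basal truncation — the
shipped runs close the energy balance to ~1e−7 %, not only for the
ν_up = π/2 variants.  Both b and an independent finite-difference ∂V/∂a are
computed so the audit is non-circular.  The boundary and volume line
integrals use 81 Simpson nodes in ν₀ (rather than the 11 nodes of the area
grid) because the energy-closure audit benefits from the extra line
accuracy at negligible cost.

Volumes: the cavity is the solid of revolution under the deformed
endocardium closed flat at the basal endocardial edge; "wall volume" is
the epicardial solid of revolution minus the cavity (this convention
reproduces the tabulated 59.8714 / 158.112 cm³ for all three reference
shapes).  The material wall volume (the |J| integral over the mapped wall,
which the mapping preserves identically) is also provided and used by the
invariance tests; it differs from the revolution construction by the
non-material wedge above the basal cone.  For the static finite-element
comparison geometry (a₀ = 5, μ_in = 0.45, μ_out = 0.62, ν_up = π/2) the
closed form gives a cavity volume of 62.5 cm³; the published description
of that configuration quotes 64.4 cm³, a discrepancy we document rather
than force (the basal-closure convention behind the quoted number is not
recoverable).

## Circulation closures

Table parameters: R_PULM = 0.023, R_SYST = 0.11, R_AO = 0.001,
R_op,mv = 0.0008, R_op,aov = 0.0005 kPa·s/cm³, C_A = 20, C_SYST = 10
cm³/kPa, P_PA = 3.0, P_SV = 6.0 kPa.  Two constants of the valve model and
the initial conditions are not published anywhere and are model closures:

* β = 50 kPa⁻¹ (sigmoid steepness: switching over ~0.1 kPa),
* R_cc = 10 kPa·s/cm³ (closed-valve leak < 1 cm³/s at physiological
  gradients),
* P_A(0) = 1.5 kPa, P_AO(0) = 10 kPa, a_i(0) = 0, cycle phase starting at
  activation onset.

Initial-condition transients decay within 4–5 cycles; all reported
quantities average cycles 6–11 of 12.  The valve constants are not
innocuous: with β = 50 a forward-biased valve retains a residual
resistance R_cc e^(−βΔp) comparable to the open value at small gradients,
which throttles early filling; sharpening the sigmoid (β = 200 at a
correspondingly finer step) raises converged stroke work by about 5%
through fuller filling while leaving the matrix dissipation essentially
unchanged.  The defaults were fixed from the stated rationale, not fitted
to any target output.

## Time integration

State y = (a₁, a₂, a₃, P_A, P_AO).  Each Heun (explicit second-order
Runge–Kutta) stage assembles M, g, b at the current state and solves the
algebraic pair (p, P_aov) — the flow constraint dV/dt = q_mv − q_aov with
ȧ = M⁻¹(bp − g) eliminated, plus the implicit proximal aortic node — by a
damped 2-variable Newton iteration (tolerance 1e−10, warm-started; a
monotone bisection fallback guards valve-transition corners).  The rates
then follow from one 3 × 3 solve, so the per-stage "4-unknown" system is
solved exactly, not iterated in time.

The baseline step is dt = 5e−4 s, refined to 5e−5 s whenever a
transvalvular pressure difference lies within 2.5/β of the sigmoid
crossover.  A 1e−3 s baseline is too coarse: the balance equations are a
stiff relaxation (small viscous M against the exponential passive
stiffness at end-diastolic strains) and an explicit step of 1e−3 s rings
visibly in the rates late in diastole.  At 5e−4 s the converged-cycle work
integrals change by < 5e−4 relative under step halving, and the observed
convergence order on smooth windows exceeds 1.8.  Steps are clipped to cycle
boundaries; work integrals accumulate trapezoidally from the powers at
accepted states; 1 kPa·cm³ = 1 mJ.

Work conventions (work done *by* the tissue positive): fiber work
−∮∭ S_f : Ė dV₀ dt includes the force–velocity contribution; viscous work
−∮∭ S_v : Ė ≤ 0 is the matrix term only; elastic net work vanishes over a
closed cycle (< 0.2% of stroke work is asserted); internal = fiber +
viscous + elastic; stroke work = −∮ p dV.

## Static passive inflation

With activation off and rates zero, b(a)p = g(a) is solved by damped
Newton with backtracking and a pressure ramp.  The converged residual
floor (~3e−9 kPa·cm³) is set by the finite-difference noise of b and g;
the default tolerance is 1e−8.  Inflating the finite-element comparison
configuration at 1 kPa expands the cavity (a₂ < 0) with small a₁, a₃ —
anisotropy induces a slight passive twist.

## Problem sizes used

Shipped runs use the 9 × 11 Simpson grid, 81-node boundary lines, 12
cycles per configuration (three matched-volume shapes plus three
equatorial-truncation rebuilds), dt = 5e−4/5e−5 s.  One 12-cycle run takes
roughly 1.5–2 minutes on a single CPU; the full acceptance recomputation
about ten minutes.

## What the shipped conditions do and do not show

All inputs are synthetic in the sense that geometry and parameters are the
tabulated reference values; no imaging data enters.  The tests therefore
establish internal correctness (kinematic identities, energy closure,
convergence, determinism) and reproduction of the published geometry and
fiber-work results under the stated parameter set — they do not establish
patient-level validity; stroke work inherits a ~5% uncertainty from the
unpublished valve closures, while the matrix-viscous dissipation follows
directly from k_vm under the stated law (its push-forward is oracle-tested)
and is insensitive to those closures.  Known limitations: axisymmetry (no
regional disease), a single LV chamber (no right-ventricular or
pericardial interaction), phenomenological activation (no excitation or
crossbridge kinetics), inertia neglected, and a fixed transmurally linear
helix-angle law.
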