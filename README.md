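# lvdyn — a low-order dynamic model of the left ventricle

`lvdyn` simulates the beating human left ventricle (LV) with three
kinematic degrees of freedom, full finite-deformation mechanics and a
lumped-parameter circulation, fast enough to run many cardiac cycles in
seconds-to-minutes on a laptop.  It is aimed at cardiovascular modellers who
need wall stress, strain, pressure and volume through the cycle — for
example to interpret speckle-tracking echocardiography or to prototype
parameter-identification loops — without the cost of a finite-element model.

## The model

The LV wall is a truncated thick-walled prolate spheroid described in
prolate spheroidal coordinates (μ, ν, φ) with interfocal half-distance *a*.
Deformation is restricted to a three-parameter family of exactly
volume-preserving mappings:

* **a₁** — base-to-apex elongation (the half-distance becomes a₀ + a₁),
* **a₂** — circumferential contraction/expansion,
* **a₃** — torsion, growing from base to apex.

The radial coordinate of a material point follows implicitly from a cubic
in cosh μ chosen so that **det F = 1** pointwise (myocardial
incompressibility).  Muscle fibers lie in surfaces of constant μ₀ and wind
helically; the equatorial helix angle runs linearly from +85° at the
endocardium to −65° at the epicardium (Streeter's transmural profile).

Stresses (second Piola–Kirchhoff) combine

* **active fiber stress** σ_ff = A(t) G(L_s) (F₀ + k_av dε_f/dt)(1 + k ε_f,ed),
  with a prescribed activation wave A, Gaussian length–tension factor G,
  linear force–velocity term and Frank–Starling preload factor,
* **passive Fung-type transversely isotropic elasticity**,
  S_e = ∂Ψ/∂E with Ψ = c₁(e^W − 1)/2,
* **Kelvin–Voigt matrix viscosity**, S_v = k_vm C⁻¹ Ċ C⁻¹.

Equilibrium is imposed in weak form and reduced (by 2-D Simpson quadrature
over the wall) to three generalized balance equations, linear in the rates:
M ȧ = b p − g, where p is the cavity pressure.  The LV couples to a
pulmonary–atrial–aortic–systemic circuit whose mitral and aortic valves are
smooth pressure-gated resistances.  Each Runge–Kutta stage solves the
algebraic unknowns (p, P_aov) by Newton iteration and advances
(a₁, a₂, a₃, P_A, P_AO) explicitly — a stiff differential–algebraic system
integrated with an adaptive step that refines while a valve switches.

## Worked example

```python
from lvdyn import ModelConfig, Simulator

res = Simulator(ModelConfig()).run(12)     # "normal" geometry, 12 cycles
w = res.work                                # per-cycle energy ledger (J)
print(w[w.cycle >= 6][["fiber_work", "viscous_work",
                       "internal_work", "stroke_work"]].mean())
```

prints (converged cycles 6–11 of the default configuration):

```
fiber_work      1.006794
viscous_work   -0.020213
internal_work   0.986558
stroke_work     0.986558
```

i.e. the fibers perform about 1.01 J per beat, of which ~0.02 J is lost to
matrix viscosity and ~0.99 J is delivered as pressure–volume (stroke) work;
the pressure–volume loop spans roughly 62–131 cm³ with peak LV pressure
≈ 16 kPa.  Internal and stroke work coincide because the boundary-work
coefficients equal the cavity-volume gradient exactly (see
`docs/methods.md`).

The same run from the shell, plus the other experiments:

```bash
lvdyn run --shape normal --cycles 12 --out out/
lvdyn static-inflate --pressure 1.0        # passive inflation equilibrium
lvdyn shapes-experiment --cycles 12        # matched-volume shape comparison
lvdyn sensitivity --fraction 0.2           # ±20% parameter sweep
lvdyn arts-compare                         # uniform-fiber-stress overlay
```

`lvdyn shapes-experiment` runs three reference geometries (spherical,
normal, ellipsoidal) built to share the same cavity volume (59.8714 cm³)
and wall volume (158.112 cm³) and reports how closely their stroke work
agrees — the pumping work depends on the wall-to-cavity volume ratio far
more than on shape, consistent with the classic uniform-fiber-stress
prediction p/σ_ff = ⅓ ln(1 + V_wall/V).

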