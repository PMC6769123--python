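# cardioemx

Fully implicit, fully coupled cardiac electromechanics on simple
programmatic geometries — built to study how the choice of *passive*
myocardial material law changes the behavior of the *mechano-electrical
feedback* (MEF), the depolarizing current carried by stretch-activated ion
channels.

## Who this is for

Computational cardiac modelers who want a compact, transparent
reference implementation of the classic monolithic
excitation–contraction–feedback loop: two primary fields (placement
**φ**, transmembrane potential Φ), phenomenological two-variable
kinetics, an active-stress split, and a stretch switch — small enough to
read, complete enough to reproduce plate/cube/ventricle benchmarks.

## The model

Mechanics (quasi-static balance of momentum, total Lagrangian) and a
monodomain potential equation are solved together:

    0  = Div(F S) + F_φ,          Φ̇ = Div(D ∇Φ) + F_Φ,

with the stress split `S = S_pas(C) + S_act(f₀, Φ)` and the source split
`F_Φ = (k_φ/k_t)(f_e + f_m)`.

* **Passive laws** (all with a sharp tension switch ϑ(λ>1) on the fiber
  term):
  - `TIC` — transversely isotropic *compressible* modified neo-Hookean:
    Ψ = Λ/2 ln²J + μ/2 (I₁−3−2 lnJ) + ϑ η/2 (I₄f−1)²
  - `TII` — transversely isotropic *nearly incompressible* polynomial law
    in isochoric invariants, with volumetric penalty κ(J−1)², κ = 10⁴ kPa
  - `HO` — orthotropic Holzapfel–Ogden exponential law (isochoric form)
    plus the same penalty
* **Excitation** — Aliev–Panfilov kinetics
  f_e = cφ(φ−α)(1−φ) − rφ, with the standard recovery law for r and the
  affine scaling Φ = k_φ φ − δ_φ (φ=0 ↔ −80 mV, φ=0.6 ↔ −20 mV).
* **Active stress** — Ṫ = ε(Φ)[k_T(Φ−Φ_r) − T], S_act = T f₀⊗f₀ / I₄f;
  with k_T = 0.49 kPa/mV the tension saturates at 49 kPa.
* **Conduction** — D = J d_iso C⁻¹ + J d_ani f₀⊗f₀/λ², faster along the
  (deformed) fiber.
* **MEF** — f_m = ϑ G_s (λ−1)(φ_s−φ): stretched tissue (λ>1) below the
  reversal potential depolarizes itself; G_s is the study's key dial.

Everything is discretized with hex8/tet4 elements, backward Euler in time
(internal variables updated inside Newton), and one monolithic Newton
iteration per step with the exact four-block Jacobian.

Units: mm / ms / kPa / mV (forces in mN).

## Worked example

Stretch-induced excitation in a rat-scale plate (10 × 10 × 1.2 mm): a
3 mN/node triangular load pulse (peak at 5 ms, gone at 10 ms) stretches
the plate center; with G_s = 15 the stretched region self-depolarizes and
an anisotropic wave sweeps the plate:

```python
from cardioemx.experiments import run_plate_benchmark
result, problem = run_plate_benchmark("small", t_end=80.0)
print(f"complete depolarization at t = {result.depolarization_time:.1f} ms")
print(result.summary[["t", "Phi_min", "Phi_max", "lam_max"]].iloc[::20])
```

prints (abridged)

```
complete depolarization at t = 44.4 ms
       t    Phi_min    Phi_max   lam_max
0    0.0 -80.000000 -80.000000       NaN
30  15.0 -79.008142 -60.266463  0.999159
60  30.0 -74.677640  -8.769844  0.993885
84  42.0 -26.120647  19.569874  0.941957
```

The fiber stretch peaks at λ ≈ 1.16 during the pulse (switching the MEF
current on), the slowest corner of the plate crosses 0 mV at ≈ 44 ms, and
the plate then contracts (λ < 1) as the active tension develops.

The same drivers run from the shell:

```bash
cardioemx run --experiment plate-small --model tic --out out/plate
cardioemx run --experiment cube       --model ho  --out out/cube
cardioemx run --experiment lv-sweep              --out out/sweep
```

Each run writes probe CSVs, a summary table, VTU snapshots (ParaView) and
a JSON manifest of every parameter.

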