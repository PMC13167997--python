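# Methods

## Model

The cornea is idealised as a thin, homogeneous, isotropic, linearly
elastic spherical shell of uniform thickness `h`, clamped at the limbus,
filled with aqueous humor at the true pressure `IOPT`. The shell is
described by its mid-surface radius `a`, the arithmetic mean of the
anterior and posterior curvature radii; forces at the two surfaces are
referred to the mid-surface, valid while `h/a` is small (the package
warns above `h/a = 0.2`).

Flattening a disc of radius `g` against the prism face balances four
forces:

* **F1 = IOPT·πg²** — the pressure thrust on the flattened disc.
* **F2 = πEhg⁴ / (2(1−ν)a³)** — the elastic reaction of the bent shell
  in the bending-dominated, small-deflection regime. The full
  bending-moment boundary-value problem is not solved here; F2 is the
  closed-form consequence used by the error formula, adopted as the
  unique form consistent with the force balance and the composite
  stiffness `K = Eh/(2(1−ν)a³)`.
* **F3 = 2πλ(a + √(a²−g²))** — the Laplace capillary adhesion of the
  annular tear meniscus under complete wetting (zero contact angle,
  appropriate to fluorescein-assisted applanation). To first order F3
  is independent of the meniscus curvature and tear-film thickness, and
  changes by under 2 % between the two prism zones across physiologic
  curvatures, which is what licenses treating it as a constant pressure
  term `p3` in the reading equations.
* **F4 = F1 + F2 − F3** — the examiner's net thrust, the quantity the
  instrument records.

The radial displacement of the flattened mid-surface is
`w(r) = a(1 − √((a²−g²)/(a²−r²)))`; the algebraically distinct reading
`w(r) = a − √(a²−g²+r²)` agrees at both endpoints and is kept only as a
comparison helper (`radial_displacement_chord_form`). Tangential
displacement is neglected.

### Dial convention (the load-bearing design choice)

The dial reading is **force divided by the standard 3.06 mm-zone area
π·g0², for both zones**. Under this convention each zone reading is
linear in `(IOPT, K)`:

```
IOPG0·g0² = IOPT·g0² + K·g0⁴ − p3·g0²
IOPG1·g0² = IOPT·g1² + K·g1⁴ − p3·g0²
```

and the 2×2 system solves in closed form to the pressure and stiffness
estimators the package implements. The alternative convention (each
zone divided by its own area) yields a different middle term and does
not reproduce the pressure formula; the test suite pins the adopted
convention by checking the closed form against a numerical
`numpy.linalg.solve` of the system on 10⁴ random reading pairs to
1e-9 mmHg.

The Young's modulus is computed as `E = 2(1−ν)·a³·K/h` from the same
system — guaranteed consistent with the pressure and error estimators —
rather than from a separately transcribed expression whose printed
grouping is ambiguous. With the default ν, `2(1−ν) = 1.03 ≈ 1`, which
reconciles the two presentations; ν is always an explicit parameter,
never silently dropped.

## Parameters

| parameter | symbol | default | units | rationale |
|---|---|---|---|---|
| inner zone radius | g0 | 1.53 | mm | half the standard 3.06 mm Goldmann applanation diameter |
| outer zone radius | g1 | 1.80 | mm | half the dual prism's 3.60 mm outer zone |
| Poisson ratio | ν | 0.485 | — | near-incompressible soft tissue; the unique value making ERR vanish exactly at the reference cornea (E = 0.16 MPa, h = 0.536 mm, a = 7.15 mm) with p3 = 4.0 mmHg |
| tear pressure term | p3 | 4.0 | mmHg | physiological tear film; set 6.6 for distilled water, 4.6 for dry eye |
| surface tension presets | λ | 0.073 / 0.044 / 0.0507 | N/m | distilled water and the physiological bound of the tear range; the dry value is back-solved from the 4.5 mN dry-eye adhesion force (derived, not a measured literature value) |
| mmHg ↔ Pa | — | 133.322 | Pa/mmHg | standard definition |

All constants are overridable per run via YAML config or CLI flags; the
loaded configuration is echoed to the log.

The zero-error reference cornea follows from these defaults rather than
being stored anywhere: h* = 2(1−ν)a³p3/(Eg0²) = 0.536 mm,
a* = (Ehg0²/(2(1−ν)p3))^⅓ = 7.15 mm, E* = 2(1−ν)a³p3/(hg0²) = 0.16 MPa.

## Numerical choices

* Zero-error roots use Brent's method (a bracketing superset of
  bisection) with `xtol = 1e-13`, resolving ERR far below 1e-9 mmHg;
  brackets expand ×2 up to 8 times, clamped to the geometric domain
  (thickness below the shell radius, curvature above thickness and the
  outer zone), before a no-root error is raised. Every root is
  cross-checked against its closed form in the tests.
* Prisms with `g1 − g0 < 1e-6 mm` raise a singular-system error: the
  estimator variance diverges as the zones merge.
* Readings implying `K < 0` (impossible for an elastic shell; they
  arise from noise) are returned with a `negative_stiffness` warning
  and quality flag rather than raised, so batch runs complete; recovery
  metrics exclude flagged records by default.
* Reading-noise propagation is the delta method; since the pressure
  estimator is affine in the readings the propagation is exact, and the
  Monte-Carlo check in the tests agrees to sampling error. With the
  default prism, σ(IOPT) ≈ 4.07·σ(reading).
* Forces and tables are kept at full precision in memory; CSV export of
  lookup tables rounds ERR to 0.01 mmHg at write time only.
* Sweep grids default to h ∈ [0.40, 0.70] mm step 0.01, a ∈ [6.5, 8.0]
  mm step 0.05, E ∈ [0.10, 0.35] MPa step 0.01 — the physiologic ranges
  with margin.

## Synthetic cohorts

`generate_cohort` draws eyes independently and uniformly (optionally
truncated-normal centred on the reference cornea, SD a quarter of the
range) from: IOPT ∈ [10, 30] mmHg (normal through ocular-hypertensive),
h ∈ [0.450, 0.650] mm, a ∈ [6.5, 8.0] mm, E ∈ [0.10, 0.35] MPa. Dual
readings are simulated noise-free, then perturbed with independent
Gaussian noise of SD 0.5 mmHg per reading (typical Goldmann
repeatability; the model itself prescribes no noise model, so this is a
package choice) and optionally quantized to the 0.5 mmHg dial step.
Generation is fully determined by the spec's seed.

What the generator emulates: the population spread of biometrics and
instrument repeatability. What it does not: correlation between
thickness, curvature and stiffness in real populations; corneal
asphericity and spatially varying thickness; viscoelastic and layered
tissue response; operator- and fluorescein-dependent contact-area
variability; diurnal IOP variation. Passing recovery tests therefore
demonstrate the *algebraic* correctness and noise behaviour of the
inversion, not clinical accuracy — which requires in-vivo validation
against manometry or contour tonometry.

## Scale of the shipped checks

The default test suite and the acceptance script run in seconds on one
CPU: round-trip properties use 10³ random eyes, the dial-convention
check 10⁴ random reading pairs, and the noise Monte-Carlo 10⁵
replicates — sizes at which the Monte-Carlo error is a few tenths of a
percent, comfortably inside the asserted tolerances.

## Known limitations

* Linear elasticity with a single effective modulus; the real cornea is
  layered, anisotropic and viscoelastic. E here is an overall average
  of the multilamellar structure under quasi-static applanation.
* Constant-pressure treatment of the tear term in the reading
  equations; the physical meniscus variant
  (`simulate_reading_meniscus`) is provided for sensitivity studies and
  differs by ~0.01–0.2 mmHg over the physiologic range.
* Rigid limbal clamping overstates physiological constraint; scleral
  rigidity and axial-length effects are out of scope.
* The apex displacement implied by the displacement field at the
  standard zone (~0.17 mm for a = 7.15 mm) is smaller than the ~0.3 mm
  figure sometimes quoted for Goldmann applanation; the discrepancy is
  recorded, not reconciled, and does not enter the reading equations.
* The error model predicts ERR decreasing with curvature radius (the
  1/a³ dependence); flatter corneas under-read. Claims elsewhere that
  the error grows with curvature contradict this monotonicity and are
  not implemented.
* The two-zone estimator trades precision for identifiability: a 0.5
  mmHg reading SD becomes ~2 mmHg on recovered IOPT. Averaging repeated
  dual readings reduces this as 1/√n.
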