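# Methods

## The model

`monofem` solves the normalized monodomain equation of cardiac
electrophysiology on a domain Ω over a time interval (0, T]:

    ∂φ/∂t − div(D ∇φ) − f(φ, r) = 0
    ∂r/∂t = g(φ, r)

where φ is the transmembrane potential normalized by the resting and
peak voltages, φ = (V_m − V_r)/(V_p − V_r); D = σ/(A_m C_m) is the
normalized conductivity tensor (mm²/ms), transversely isotropic about a
fiber direction f: D = d_t I + (d_l − d_t) f⊗f; and (f, g) are the
modified Aliev–Panfilov reaction kinetics

    f(φ, r) = c1 φ (φ − α)(1 − φ) − c2 r φ
    g(φ, r) = (γ + μ1 r/(μ2 + φ)) (−r − c2 φ (φ − b − 1)).

Zero-flux (natural) boundary conditions are used in every shipped
experiment; Dirichlet data is supported by row/column elimination for
verification solves. Initial conditions are φ = 0 and r = 0.1146 (the
steady-regime initialization of this parameter set).

Default parameters: α = 0.05, c1 = 52, c2 = 8, μ1 = 0.1, μ2 = 0.3,
b = 0.25, γ = 0.002, V_r = −85 mV, V_p = 15 mV.

### Kinetics time scale

`IonicParams.time_scale` (τ, ms per model time unit) divides both rate
functions. With τ = 1 the formulas above are per-millisecond rates; this
is the package default for the raw kinetics API. The *protocols* default
to τ = 12.9, the classical dimensionless-to-millisecond conversion of
this two-variable model family, because only that calibration is
simultaneously consistent with the benchmark quantities the package
verifies against:

| quantity (D = 0.0952 mm²/ms) | τ = 1 | τ = 12.9 |
|---|---|---|
| converged plane-wave CV | ≈ 135 cm/s | ≈ 37 cm/s |
| depolarization front width | ≈ 0.3 mm | ≈ 4 mm |
| APD50 (single cell) | ≈ 14 ms | ≈ 189 ms |

A 37 cm/s conduction velocity with a ~190 ms action potential is the
physiological regime in which coarse meshes (h ≈ 1 mm) are meaningful
and an S1–S2 interval of 280 ms falls in the vulnerable window; with
τ = 1 the 0.3 mm front cannot be resolved by millimeter meshes at all
and tissue is fully recovered long before any premature stimulus.
The independent 1-D finite-difference check of the converged CV is part
of the test suite's design history; the package's own rod study
reproduces 37.2 cm/s at its finest mesh.

Externally applied stimulus currents are physical rates (1/ms) and are
*not* divided by τ.

## Spatial discretization

Structured hexahedral meshes of axis-aligned boxes: per axis,
⌊L/h⌋ elements of size h plus one shrunken boundary-fitted element when
L is not a multiple of h (an axis shorter than h gets a single element).
Coordinates are mm, node indexing 0-based.

Three isoparametric element families on the reference cube [−1, 1]³:

| family | nodal DOFs | internal modes | quadrature |
|---|---|---|---|
| Q1 | 8 (trilinear) | — | 2×2×2 Gauss |
| Q1NC | 8 (trilinear) | 3 incompatible modes | 2×2×2 Gauss |
| Q2 | 27 (triquadratic) | — | 3×3×3 Gauss |

The incompatible (Wilson) modes M_c = 1 − ξ_c² vanish on all element
faces, so they enrich the element interior with quadratic content
without adding globally shared unknowns; inter-element continuity is
deliberately violated in element interiors only. Mode gradients are
pushed forward with the per-quadrature-point Jacobian of the standard
isoparametric map (plain Wilson modes, no centroid-Jacobian Taylor
correction: all meshes here are regular boxes, where the two coincide).
Basis functions compose with the inverse isoparametric map; the geometry
map is trilinear for every family (sub-parametric for Q2 — exact on box
meshes). Consistent mass matrices are used throughout; no lumping or
under-integration anywhere. Note one consequence of the prescribed
2×2×2 rule for Q1NC: the quartic mode-mode mass term W_c W_d is
under-integrated (the rule is exact only through cubic terms per axis);
this is part of the element definition, and the symbolic-integration
oracle in the tests therefore targets the exactly integrated blocks.

## Time discretization and static condensation

The semi-implicit (IMEX) scheme evaluates diffusion at t_{n+1} and
reaction at t_n; the gating ODE advances by forward Euler, held at each
quadrature point. Per element this yields constant blocks K_u (nodal),
L (mode–nodal coupling) and K_α (mode–mode), each of the form
mass/Δt + stiffness. The internal coefficients are eliminated by the
Schur complement A_e = K_u − Lᵀ K_α⁻¹ L, the global matrix A is
assembled once, and — since it is state-independent — factorized once
with a sparse direct LU (SuperLU, symmetric-mode minimum-degree
ordering) and reused at every step. A dense inverse is never formed.
For systems above 20,000 nodes the direct back-solve dominates the step
cost (3-D factors fill superlinearly), so the stored factorization is
replaced by a once-computed incomplete-LU preconditioner with a
conjugate-gradient solve converged to a relative tolerance of 1e-10 per
step — the same linear algebra to solver precision, still fully
deterministic.
After each solve the internal coefficients are recovered element-locally
as α_{n+1} = K_α⁻¹ p_α − K_α⁻¹ L u_{n+1}. With Δt fixed this makes one
step: one right-hand-side assembly, one triangular solve, one small
batched recovery, one pointwise gating update.

The fully-implicit comparator is backward Euler solved by Newton with
the analytic reaction Jacobian ∂f/∂φ. The internal coefficients remain
explicit unknowns in the monolithic Newton system: the element-level
condensation above is derived for the linear semi-implicit update and
does not carry over once the reaction at t_{n+1} couples α nonlinearly.
Gating is staggered — at each Newton iterate the backward-Euler gating
equation (quadratic in r) is re-solved per quadrature point by a few
vectorized Newton iterations. Convergence is declared when the inf-norm
of the Newton update falls below `newton_tol` (default 1e-10 on the
dimensionless potential).

Numerical notes: the semi-implicit update is unconditionally stable in
its linear part (verified up to Δt = 1 ms); the practical Δt limit comes
from the explicit reaction. Both schemes are first-order accurate in
time; their one-step difference is O(Δt²), which is why they agree on
conduction velocities to well under 1% at the small steps used here.

## Stimuli

Volume stimuli add a normalized rate (1/ms) to the reaction integrand at
every quadrature point inside an axis-aligned region; surface stimuli
contribute a boundary load amplitude × ∫ N_a ds over a named face set
(the incompatible modes vanish on faces and receive no boundary load).
Amplitudes quoted in mV-based units are normalized by V_p − V_r =
100 mV: 20 mV/ms → 0.2 /ms, 12 mV/(ms·mm²) → 0.12 mm/ms. The quoted
equivalence 20 mV/ms ≙ 28,000 µA/cm³ fixes the conversion for current
densities (1400 µA/cm³ per mV/ms), used by the cuboid protocol's
50,000 µA/cm³ corner stimulus (≈ 0.357 /ms).

## Shipped experiments and design choices

**Rod (plane-wave CV).** 25 mm rod, cross-section one element of size h
per transverse axis (the plane wave is invariant transversely, so the
CV is unaffected by this unstated dimension). Isotropic D =
0.0952 mm²/ms. Stimulus: 0.2 /ms for 2 ms over a fixed 1 mm deep end
region — a fixed depth rather than "one element layer", so the injected
charge and hence wave initiation are identical across the refinement
sweep (with a per-element layer the charge scales with h and fine
meshes fail to ignite). Probes at x = 18 and 22 mm; activation time is
the first discrete sample with φ > 0.5 (no sub-step interpolation — an
optional linear-interpolation mode exists but is off by default); CV =
4 mm / Δt_activation, reported in cm/s (1 mm/ms = 100 cm/s). At
dt = 0.005 ms the quantization error on CV is below 0.1%.

**Cuboid benchmark.** 20 × 7 × 3 mm, fibers along the 20 mm axis,
d_l = 0.0952, d_t = 0.0126 mm²/ms, 1.5 mm corner-cube stimulus for
2 ms. The activation profile is read along the corner-to-corner
diagonal: nodes within half an element size of the diagonal line,
sorted by arc length; profiles from different meshes are compared after
linear resampling onto a shared distance axis.

**Spiral (S1–S2).** 50 × 50 mm slab realized as a one-element-thick 3-D
box with zero-flux faces (exactly reproduces 2-D dynamics; the element
formulation is inherently 3-D). S1: 0.12 mm/ms surface flux on x = 0
for 2 ms; S2: 0.15 /ms volume stimulus in the quadrant x, y < 25 mm
during 280–285 ms; Δt = 0.005 ms; isotropic D = 0.0952 mm²/ms (the
benchmark's longitudinal value; the slab conductivity is otherwise a
free parameter). Under the physiological calibration the S1 wavefront
reaches the far border at ≈ 140 ms and the S2 falls at the end of the
refractory tail, producing wavebreak and reentry when the local CV is
accurate — which is exactly what separates the element families on a
1 mm mesh.

## Problem sizes used in the shipped studies

The test suite and the acceptance script run desk-scale versions of the
studies: rod meshes down to h = 0.05 mm (500 elements; runs stop once
both probes activate), the cuboid at h = 0.8 mm against a Q1 baseline
of h = 0.2 mm at Δt = 0.02 ms,
and the coarse spiral pair (h = 1 mm, 120,000 steps each) at full
600 ms duration. Finer baselines (h = 0.1 mm cuboid/spiral) behave
identically in trend but are outside desk scale; mesh-refinement and
time-refinement convergence of the schemes is established by the
property tests instead.

## What the verification shows — and what it does not

All inputs are generated procedurally (structured meshes, protocol
configurations); there is no measured data anywhere, so passing tests
show correctness of the discretization and implementation against the
stated model, not predictive validity for real tissue. The geometries
are regular boxes: behavior on distorted or unstructured hexahedra is
exercised only by the distorted-element unit tests, not by a full
simulation. The rod's cross-section and conductivity and the slab's
conductivity are not part of the benchmark definitions and were fixed
as described above. Spiral-tip trajectory analysis and anatomically
realistic ventricular geometries are out of scope.

## Known limitations

* Fiber fields are globally constant per run (sufficient for the box
  benchmarks; no per-element fiber input yet).
* The fully-implicit path assembles and factorizes its Newton matrix at
  every iteration; it is a verification comparator, not tuned for speed.
* Q2 output decomposes each element into 8 trilinear VTK sub-cells;
  viewers see the correct nodal values but quadratic edges are not
  curved in the export (irrelevant on box meshes).
* `stop_when="all_activated"` polls every 20 steps, so recorded final
  times can overshoot the last activation by up to 20 Δt.
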