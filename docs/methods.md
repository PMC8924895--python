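# Methods

This note documents the models, algorithms and numerical choices behind
`ionwater`, what the synthetic data generator does and does not emulate,
and the known limitations.

## Energy model

The package evaluates a polarizable, bottom-up ion–water interaction of
the extended-TTM family. For a halide anion X⁻ and n water molecules the
total energy is assembled as

    V_n = V_W^intra + V_WW^inter + V_iW^inter,

and the ion–water intermolecular part as

    V_iW = V_rep + V_disp + V_elec + V_ind.

**Born–Mayer repulsion.** `Σ A_i exp(−β_i R_i)` over the ion–O and ion–H
pairs, A in kcal/mol, β in Å⁻¹, both stored positive. A ≥ 0 and β > 0 are
enforced at construction.

**Damped dispersion.** `−Σ C6_i f6(δ_i R_i)/R_i⁶` with the sixth-order
Tang–Toennies function `f6(x) = 1 − e^(−x) Σ_{k≤6} x^k/k!`, evaluated as
the regularized lower incomplete gamma function P(7, x), which is that
series identically (numerically robust at any x; the test oracle is an
independent 50-digit Decimal series). The damping order is fixed at 6 to
match the R⁻⁶ term. By default δ = β (the damping steepness tracks the
repulsion exponent); an explicit δ can be set per pair.

**Electrostatic sites.** Each water carries two positive charges on the
hydrogens and a compensating negative charge (−2q_H) on a massless M site
displaced from the oxygen along the HOH bisector toward the hydrogens
(default offset 0.147 Å, expressed as `m_site_fraction` of a reference
offset so it can be scaled). The ion carries −1 e. Polarizable sites sit
on O, H and the ion; the M site carries charge only.

**Charge smearing.** All charges are Gaussian-smeared. This is a
deliberate model choice: Gaussian densities give closed-form screening for
every interaction — `erf(R/γ)/R` for charge–charge, the λ₃ factor
`erf(x) − (2x/√π)e^(−x²)` for fields, and `[3 r̂r̂ λ₅ − I λ₃]/R³` for
dipole–dipole — with the exact pair-width combination
`γ_ij = sqrt(w_i² + w_j²)` and an exact point-charge limit as widths → 0
(an invariant the test suite checks). The dipole width of a polarizable
site is `thole_damping · α^(1/3)`; site pairs inside one monomer use an
increased damping width (`intra_thole_scale`, default 3), the TTM-style
remedy against overpolarization between bonded sites.

**Induced dipoles.** Polarizable sites satisfy
`μ_i = α_i (E_i⁰ + Σ_j T_ij μ_j)` with the Thole-damped tensors above,
solved either by damped fixed-point iteration (mixing 0.65, stop when the
per-step change falls below a tenth of the 10⁻⁸ e·Å tolerance — the step
size underestimates the distance to the fixed point by the contraction
factor) or by a direct dense solve of `(α⁻¹ − T) μ = E⁰`. The direct path
verifies positive-definiteness by Cholesky and reports a polarization
catastrophe otherwise; the default "auto" mode falls back from iteration
to the direct solve. `U_ind = −½ Σ μ_i·E_i⁰ ≤ 0` always. For clusters the
dipoles are solved over the full site set (ion + all waters), so the
induction is many-body; the ion–water induction contribution is the full
system value minus the water-only value at the same geometry.

**Interaction energy.** `ΔE = E(X⁻(H₂O)ₙ) − E((H₂O)ₙ) − E(X⁻)` at fixed
geometry. The isolated classical ion has zero internal energy, so ΔE
collapses to the ion–water intermolecular energy; both routes are
implemented and tested against each other.

**Water models.** Water–water terms enter through a pluggable interface:
a model supplies (intramolecular energy, intermolecular non-induction
energy, site charges, site polarizabilities). The registered names
(i-TTM2/3/4, i-MBpol, custom) all resolve to `SimpleRigidWater`, a
simplified reference model with fixed charges, harmonic monomer
distortion (SPC/Fw-like force constants about r_OH = 0.9572 Å,
HOH = 104.52°), smeared water–water electrostatics, and an O–O
Born–Mayer + damped-dispersion pair term. It is deliberately not a
re-implementation of the published TTM2/TTM3/TTM4-F or MB-pol water–water
potentials, whose parameter tables are outside this package's scope; a
user-supplied water potential can be registered under any name.

**Units and conventions.** Å, kcal/mol, elementary charges, Å³
polarizabilities; Coulomb constant 332.0637157 kcal·Å/(mol·e²); IUPAC
standard atomic weights for centers of mass; atoms 0-indexed internally
and 1-indexed in report tables.

## Training data

Dimer training sets live on grids equidistant in R (ion–O distance,
default 2–8 Å), θ (polar angle from the water C2v axis) and φ (azimuth),
10×10×5 = 500 points by default. The water-fixed frame puts O at the
origin, the C2v axis along z with the bisector toward −z and H in the
xz-plane; water's mirror symmetry makes φ ∈ [0°, 180°] non-redundant.
Weights follow `w(E) = (E − E_min + D_E)⁻²`, maximal at the training-set
minimum; D_E defaults to 2 kcal/mol.

The synthetic-reference generator evaluates a known ground-truth
parameter set on the grid and adds i.i.d. Gaussian noise (default 0; the
noisy study condition is 0.05 kcal/mol), recording the parameter hash,
seed and noise level in the set's provenance. It emulates the *size,
layout and noise scale* of an ab initio dimer-energy campaign. It does
not emulate: correlated basis-set or CP-correction errors, geometry
relaxation, many-body reference data, or model inadequacy (the truth lies
inside the fitted family except where a test injects an explicit
mismatch term). Passing recovery tests therefore demonstrates that the
estimator pipeline is correct and well-conditioned — not that the
functional form suffices for real coupled-cluster data.

## Fitting

For fixed exponents the model is linear in (A_O, A_H, C6_O, C6_H)
because electrostatics and induction carry no fitted parameters, so each
objective evaluation solves the linear subproblem exactly by weighted SVD
least squares (relative singular-value cutoff 10⁻¹⁰; negative A or C6 are
clipped to zero, as both are non-negative by construction) and Nelder–Mead
runs only over log β (positivity by construction; xatol 10⁻¹⁰,
fatol 10⁻¹², one restart from the best vertex on stagnation, never
returning an ascent).

**Active learning.** Each iteration minimizes χ², measures unweighted
per-point errors, and — if neither the mean-error nor the max-error
tolerance holds — multiplies the weights of points with
`|err| > threshold · max|err|` (threshold default 0.5) by
`1 + γ₀ d^t` (γ₀ = 1, d = 0.7), a boost that shrinks over iterations,
then renormalizes weights to mean 1 so χ² magnitudes stay comparable. The
RMS error must not increase across accepted iterations; a worsening
iterate is rejected and the loop halts. With threshold > 1 no boost ever
fires and the loop degenerates to a single weighted fit — the baseline
used in the paired comparison.

**Two-stage protocol.** Stage 1 estimates the dispersion coefficients on
the long-range set (undamped −1/R⁶ columns; damping ≈ 1 and repulsion
negligible there). Stage 2 freezes C6 and fits (A, β) with active
learning. The pair of stages iterates to self-consistency (default 2
cycles; the recovery protocol uses 8): refinement passes subtract the
currently fitted repulsion and damp the columns at the fitted exponents,
which lets them use mid-range points (R ≥ 4 Å by default). This matters
under noise: on the far tail alone the two 1/R⁶ columns are nearly
collinear and the dispersion signal sits at the noise floor, so the O/H
coefficient split is unidentifiable there — measured errors exceeded 100%
at 0.05 kcal/mol noise — while the mid-range window, legitimate once the
repulsion is being subtracted, brings the split under control. Stage 2
never alters the C6 values it receives.

The recovery protocol finishes with one joint active-learning fit of all
four linear coefficients (A and C6 together) started from the staged
optimum: the staged estimate anchors the asymptotics and supplies the
exponents, while the joint linear solve over the full weighted set is the
efficient estimator of the coefficient split under noise (measured
worst-parameter replicate errors drop from a heavy ~8%-SD tail to a few
percent). On noiseless data the polish is a no-op at the exact solution.

## Structure optimization

Self-adaptive evolutionary programming. Individuals are (χ, η) pairs;
mutation is `χ' = χ + s_g η N_j(0,1)`, `η' = η exp(τ′N + τ″N_j)` with
τ′ = 1/√(2n), τ″ = 1/√(2√n) by default, and the generation-decay step
scale `s_g = δ₀ δ_j^g` (δ₀ = 0.15, δ_j = 0.85; a literal mode using ×0.15
per generation is available). Survivors of the joint 2M pool are chosen
by q-opponent tournament (q = 10 default; wins on ≤, ties broken by lower
energy then pool order, which guarantees the best individual survives).
The population is M = 100; convergence uses the 0.01 kcal/mol best-energy
threshold.

The decaying schedule quenches the search after roughly 45 generations
with about 1 Å of total path length — enough to refine a good seed, too
little to relax a random cloud (and η, left to its log-random walk,
inflates once the schedule has collapsed). The optimizer therefore also
runs the schedule in **annealing waves** (`n_cycles > 1`): each wave
replays the decay from a fresh population seeded around the incumbent
best (elite individual carried over, η reset to 1) with a kick amplitude
that shrinks by 0.6 per non-improving wave down to a 0.02 Å floor; the
run converges after `cycle_patience` (default 4) consecutive waves that
fail to improve the best energy by the threshold. `n_cycles = 1` is the
plain single-schedule algorithm. `global_minimum_search` adds the
protocol layer: one annealed run per seed configuration (mirroring
substitution seeding, where each water position donates one initial
structure) plus a final small-kick polish run, all seeded
deterministically from one master seed.

Water monomers move as rigid bodies by default (translation +
rotation-vector genes about each oxygen) so rigid-water potentials stay
valid; a fully flexible Cartesian mode is used for point-particle systems
such as the Lennard-Jones validation clusters (LJ₄ tetrahedron at −6 ε;
LJ₇ at −16.5054 ε, cross-checked against a multistart BFGS oracle).

## Benchmark protocol

Per-structure interaction energies for each method are ingested from TSV
(electronic-structure values are never computed here) or evaluated from a
model. Deviations are `δ = 100 (E_method − E_ref)/|E_ref|` — the |E_ref|
denominator is a documented convention — summarized per halide as
max/mean |δ|; scans use the mean absolute error over identical scan
points; "normalized" average errors divide each panel (one per ion or per
scan) by its maximum so the worst method sits at 1 (all-zero panels stay
at 0). Structures missing from a table are reported, never imputed.
Reports are pure functions of their inputs and write byte-identical TSVs;
plots are a thin optional layer over the tables.

Ion-displacement scans place the ion at `COM + s (r_ion − COM)` for a
step schedule (default 0, 0.2, …, 1.5): s = 0 is the center of mass,
s = 1 the minimum-energy position, s > 1 the dissociative region. Water
coordinates never move. The surface-plane analysis measures signed
distances of every oxygen and the ion from the plane through the COM
perpendicular to the COM–ion line (positive toward the ion); whether the
COM includes the ion mass is a flag (default: include).

## Numerical choices and degenerate inputs

- Pair interactions below 10⁻⁸ Å separation, ions at the center of mass,
  and degenerate HOH bisectors raise specific geometry errors rather than
  returning garbage.
- Monomer detection assigns each H to its nearest O within a 1.3 Å
  cutoff (covers distorted monomers, excludes ~1.7 Å hydrogen bonds) and
  rejects ambiguous assignments (second O within the cutoff at < 0.2 Å
  distance difference) and oxygens with ≠ 2 hydrogens.
- The XYZ dialect is the plain two-header-line format; an `E=<float>`
  token in the comment line round-trips as an energy tag; coordinates are
  written with 10 decimal places (round-trips far below the 10⁻⁶ Å
  contract).
- All randomness flows through `numpy.random.Generator` objects seeded
  explicitly; EA draws are consumed in a fixed documented order
  (coordinate draws, shared η draw, per-gene η draws), so identical seeds
  give identical results.

## Default parameter sets

The shipped per-halide parameter sets (Born–Mayer amplitudes and
exponents, C6 coefficients, q_H = 0.574 e, Gaussian widths 0.4–0.6 Å,
α_O = 0.837 Å³, α_H = 0.496 Å³, coupled-cluster-derived anion
polarizabilities 2.47/5.48/7.27/10.27 Å³ for F⁻/Cl⁻/Br⁻/I⁻) are the
package's own synthetic study conditions, chosen once to give physically
sensible dimer minima (e.g. Cl⁻(H₂O) binds ≈ 16.7 kcal/mol at
R(Cl–O) ≈ 3.25 Å on the hydrogen side) and well-scaled fitting problems.
They are starting points and fixture ground truths, not published fits;
production work should refit them to ab initio data via `ionw fit`.

## Limitations

- No analytic gradients or forces; the optimizers here are
  derivative-free by design. No periodic boundary conditions or Ewald
  summation — finite clusters only.
- The simplified reference water model is qualitative; quantitative
  water–water energetics require registering a real water potential.
- Geometry-dependent water charges (dipole-moment-surface charges) are
  not implemented; the charge provider is fixed-charge rigid-water by
  default.
- The EA's annealing-wave layer makes no guarantee of finding global
  minima; reliability comes from multistart seeding, and for large
  clusters multiple low-lying structures should be retained rather than
  a single "the" minimum.
- Counterpoise/BSSE handling, dispersion-correction evaluation (D3/D4)
  and any electronic-structure execution are out of scope; such energies
  are benchmark *inputs*.
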