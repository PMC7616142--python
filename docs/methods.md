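# Methods

## Model

`mshell` implements a morphoelastic Kirchhoff–Love-type theory for thin,
incompressible (neo-Hookean) axisymmetric cell sheets whose *intrinsic*
meridional radius of curvature may become comparable to the sheet
thickness — the regime of cell wedging that drives tissue invagination.
Cell shape changes enter as an intrinsic configuration: locally
stress-free stretches f_s⁰(s), f_ϕ⁰(s) and curvatures κ_s⁰(s), κ_ϕ⁰(s)
prescribed along the undeformed arclength s of a spherical shell of
radius R (all lengths hereafter in units of R, energies in units of
C·R³ with C the neo-Hookean modulus). The intrinsic metric is in general
incompatible, so the equilibrium shape carries residual stress.

The central dimensionless field is the large-bending parameter

    η(s) = κ_s⁰ t / (2 g⁰),      g⁰ = f_s⁰ f_ϕ⁰,  t = εh (thickness),

half the intrinsic meridional curvature times the intrinsic thickness.
|η| → 1 is the *constriction limit* of fully wedge-shaped cells: one
shell surface contracts to a point, the theory's moduli diverge like
(1−|η|)⁻², and evaluation is refused beyond a guard (see below).

### Energy density

With physical shell strains e_s = (f̃_s−f_s⁰)/f_s⁰, e_ϕ = (f̃_ϕ−f_ϕ⁰)/f_ϕ⁰
and alternative curvature strains

    K_s = (f̃_s κ̃_s − f_s⁰ κ_s⁰)/((f_s⁰)² f_ϕ⁰),
    K_ϕ = (f̃_ϕ κ̃_ϕ − f_ϕ⁰ κ_ϕ⁰)/(f_s⁰ (f_ϕ⁰)²),

(which vanish for pure stretching, unlike the raw curvature differences
L_s, L_ϕ, kept for diagnostics), the energy per unit undeformed area is
the quadratic form

    ê = ½{ t [ᾱ_ss e_s² + 2ᾱ_sϕ e_s e_ϕ + α_ϕϕ e_ϕ²]
         + 2t² [β̄_ss e_s K_s + β̄_sϕ e_s K_ϕ + β_ϕs e_ϕ K_s + β_ϕϕ e_ϕ K_ϕ]
         + t³ [γ_ss K_s² + 2γ_sϕ K_s K_ϕ + γ_ϕϕ K_ϕ²] },

whose eleven moduli are functions of η alone (`mshell.coefficients`).
This "physical-strain" bookkeeping is algebraically identical, symbol by
symbol, to the asymptotic form in scaled strains E = e/ε and thickness
h = t/ε, because ε³hE² = t(εE)²/ε²·… collapses exactly; a unit test
verifies the mapping numerically. At η = 0 the form reduces to the
classical Hookean shell density

    ê₀ = 2[t(e_s² + e_s e_ϕ + e_ϕ²) + (t³/12)(K_s² + K_s K_ϕ + K_ϕ²)],

i.e. Poisson ratio ν = ½ (incompressibility), Young's modulus E = 3C,
stretching modulus 4Ct, bending modulus Ct³/3, and no stretch–curvature
coupling. The `model` switch ("large_bending" vs "classical") selects
which form the solver minimizes; "classical" simply evaluates the moduli
at η = 0.

Two closed-form excess identities connect the models: the stretching
excess ∝ η²(2−η²)(1−η²)⁻²(2e_s+e_ϕ)² is nonnegative (the classical
theory always underestimates stretching, except on the special direction
e_ϕ = −2e_s), while the bending excess
∝ η²(3−2η²)(1−η²)⁻²(3K_s+K_ϕ)(k(η)K_s+K_ϕ) can be negative in the wedge
k(η)|K_s| < |K_ϕ| < 3|K_s| with K_sK_ϕ < 0. The multiplier k(η) rises
from 13/5 at η=0 to 3 at |η|=1; its printed closed form is
sign-ambiguous in our source, so it is *re-derived* symbolically by
factorizing the bending excess (`asymptotics.reconstruct_k`) and
accepted only because it reproduces both endpoint values. Both excess
formulas are cross-checked against direct large-minus-classical
differencing to 1e-9 relative.

### Through-thickness asymptotics

Leading-order intrinsic volume conservation gives the transverse profile
Z⁰(ζ) = (1−√(1−2λ_s⁰ζ))/λ_s⁰ and surface offsets
h± = (H⁰/2)(1 ∓ λ_s⁰H⁰/4) with h⁺+h⁻ = H⁰ exactly. The leading-order
force balance yields the Kirchhoff result — midsurface normals remain
normal (Z₍₀₎ ≡ Z⁰, S₍₀₎ ≡ 0) with transverse pressure multiplier
p₍₀₎ = 1 — which the oracle verifies by *integrating the governing ODE
system numerically* rather than assuming the closed form. The
first-order incompressibility correction Z₍₁₎ is implemented from its
closed form and verified symbolically against the reconstructed O(ε)
incompressibility relation (residual exactly 0 in sympy).

## Numerics

**Coefficient evaluation.** The closed forms contain tanh⁻¹η/ηⁿ
cancellations; below |η| = 0.05 (0.15 for k, whose numerator cancels
through η⁵) evaluation switches to Taylor series frozen from the
symbolic oracle (order 12). Both branches agree with 40-digit reference
values to ~1e-13. tanh⁻¹ is evaluated as ½log((1+η)/(1−η)); a guard band
raises a constriction error for |η| > 1 − 1e-6.

**Discretization.** Uniform grid in undeformed arclength (default
n = 401 for single solves), tangent angle ψ̃ and meridional stretch f̃_s
as unknowns; ψ̃ pinned to 0 and π at the poles; r̃ by cumulative
trapezoid of f̃_s cos ψ̃; κ̃_s = ψ̃′/f̃_s with second-order differences;
κ̃_ϕ = sin ψ̃/r̃ with the removable pole limit κ̃_ϕ → κ̃_s. The energy is
integrated by composite Simpson against the undeformed radius r(s) =
sin s, which vanishes at the poles and suppresses the coordinate
singularity there. Field accuracy is O(Δs²) (set by the trapezoid radius
reconstruction); the pole displacement of the early-invagination
scenario changes by < 0.1% between n = 201 and n = 401.

**Equilibrium.** Closure of the shell, ∫f̃_s cos ψ̃ ds = 0, is an
equality constraint. Globalization by an augmented-Lagrangian outer loop
around L-BFGS (analytic gradients, including the adjoint of the
cumulative-trapezoid radius map), followed by Newton iteration on the
KKT stationarity system (dense forward-difference Jacobian of the
analytic gradient) to drive the residual below ~1e-11. The solve is
deterministic given the initial iterate (identity embedding by default).
The axial gauge pins z̃ at the anterior pole, so the posterior-pole
displacement d = z̃(0) − z(0) is read directly; d > 0 means invagination
(posterior pole moving toward the anterior). Where d is measured is a
convention of this package — the source defines it only pictorially.

**Refusal margin.** Large-bending solves refuse intrinsic data with
max|η| > 1 − margin (default margin 0.02, the scale at which the
asymptotics loses validity for t = 0.15); the margin is overridable, and
configurations within 0.02 of the limit trigger a warning rather than an
error when explicitly allowed. The late-invagination parameter set
(max|η| ≈ 0.797) is inside the default margin.

**Continuation.** Branches in k = −κ_b are traced by pseudo-arclength
continuation of the bordered stationarity system (unknowns: fields,
closure multiplier, k; bordered finite-difference Jacobian, secant
tangent, adaptive step). This follows the branch around saddle-node
folds, including the energetically unstable side. Folds are flagged by
sign changes of Δk along the branch and refined by a local quadratic fit
of k against branch arclength. Defaults for branch work: n = 201 grid
(151 for bisection), step 0.1 ≤ h ≤ 0.25.

**Critical width.** The fold retreats toward the constriction line
k = 2g⁰/t ≈ 10.67 (g⁰ of the bend region) as the bend-region width w
shrinks, so "fold onset" is defined over each model's *admissible* sweep
range: the classical theory, which has no constriction singularity, is
swept to the line itself, while a large-bending branch terminates at its
validity guard max|η| > 1 − margin. A fold that the large-bending
geometry pushes beyond the constriction guard therefore does not count —
which is precisely the stabilization mechanism: near the fold the bend
region approaches full cell wedging, and the diverging large-bending
moduli postpone the turning point relative to the classical theory (at
w = 0.9 the folds sit at k ≈ 9.65 vs ≈ 9.35). Bisection on w (default
tolerance 0.025) locates the onsets w* (large-bending) > w₀*
(classical); the separation is a few hundredths of R in w with the
default invagination parameters. When both models are restricted to a
*common* window well inside the guard, the onsets coincide within the
bisection tolerance — the stabilization lives near the constriction
limit, where only the large-bending theory distinguishes itself.

## Synthetic scenario generator

`volvox_intrinsic` builds the invagination program of a spherical
embryo: a bend region [s₀−w, s₀] of wedge-shaped cells with intrinsic
curvature κ_b < 0, a posterior region of meridionally narrowed cells
(f_s⁰ = f_p < 1 for s < s₀), and an unchanged anterior. Defaults are the
published early-invagination parameters (κ_p = κ_a = 1, κ_b = −2,
f_p = 0.8, f_a = 1, s₀ = 1.5, w = 0.2, t = 0.15, the thickness
appropriate for *Volvox globator*). Step discontinuities are regularized
by logistic transitions of width δ = 0.05 (small against w yet resolved
by the default grid; the source states only that steps are regularized).
Two conventions are genuinely open in the source and fixed here:
f_ϕ⁰ = 1 (cells narrow meridionally, not azimuthally) and κ_ϕ⁰ without
bend amplification (only the meridional curvature is scaled up); both
are overridable through explicit profile CSVs. What the generator does
*not* emulate: cell-level discreteness and noise, active contractility
dynamics, contact/self-intersection of the fully inverted shell, and the
later inversion stages (anterior thinning, peeling). Passing tests
therefore validate the continuum theory and its solver, not the full
biology of inversion.

## Known limitations

- The inverted (post-fold) branch is traced without contact handling, so
  it persists to k → 0 and no lower turning point appears: folded
  branches show a single fold inside the sweep window (hysteresis
  without a closing S within the window).
- Accuracy of strain fields is second order in the grid spacing; near
  the poles κ̃_ϕ relies on the regularized limit.
- The theory itself loses asymptoticity as |η| → 1; results within
  ~0.02 of the limit carry a warning and should be read qualitatively.
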