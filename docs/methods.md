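# Methods

`pactoed` implements a virtual two-dimensional quantitative photoacoustic
computed tomography (qPACT) system and an estimator-independent pipeline
that ranks illumination designs by a Monte-Carlo estimate of the Bayesian
Cramér–Rao bound (the Van Trees inequality) on the reconstruction error of
the optical absorption coefficient. This note records the models, the
numerical choices behind them, and what the shipped tests do and do not
establish.

## Imaging model

**Domain and discretisation.** The object is supported on a disk Ω of
radius 5 cm centred at the origin. All fields are first-order continuous
Galerkin (P1) functions on an unstructured triangular mesh; units are
centimetres and seconds throughout, with fluence in AU normalised to the
ANSI exposure ceiling. The mesher places nodes on concentric rings whose
spacing follows a sizing law interpolating linearly in radius between a
boundary diameter `h_boundary` and a centre diameter `h_center`
(0.08 → 0.15 cm for the study-scale mesh, giving ≈ 8.1k nodes), then runs a
Delaunay triangulation; an optional user sizing function allows local
refinement (used by the Radon-oracle test to resolve a discontinuous
field). Mesh generation is deterministic given its seed. Boundary normals
are computed per edge from the mesh geometry rather than the analytic
circle, so perturbed domains would work unchanged.

**Optics.** The fluence φ solves the diffusion approximation with a Robin
boundary condition,

    μ_a φ − ∇·(D ∇φ) = 0 in Ω,   ⟨D∇φ, η⟩ + φ/2 = 2q on ∂Ω,

with D = 1/[3(μ_a + μ_s′)] and matched refractive indices (hence the exact
1/2 and 2 coefficients). The absorbed energy density is h = Γ μ_a φ with the
Grüneisen parameter Γ ≡ 1 (a single greppable constant). Products of nodal
fields (μ_a = μ̄_a e^{m1}, h = μ_a φ) are formed nodally — the interpolatory
convention consistent with P1 accuracy that also keeps the adjoint
expressions simple. The system matrix is SPD; one sparse factorisation per
parameter value serves every illumination and the adjoint solves. Against
the closed-form modified-Bessel radial solution of the homogeneous-disk
Robin problem, the solver shows second-order L² convergence (0.08% at study
sizing, 0.02% one refinement finer).

**Illumination.** Each cone-beam source contributes
`P g(θ) e^{−μ_a′ r}/(4π r²)` along the ray towards the boundary point, with
`g(θ) = cos θ · 1(|θ| < β/2)`, aperture β = 25°, exterior absorption
μ_a′ = 10⁻³ cm⁻¹, and θ measured between the source axis and the ray from
the source. The monopole kernel is used exactly as printed (no 2D
re-derivation). The nodal boundary flux is the inward projection of the
summed source fluxes clamped at zero, entering the weak form through the
boundary mass matrix. Two 10-source, 4-illumination layouts are built in:
*contiguous* (uniform on a 90° arc, rotated by π/2 per illumination) and
*interlaced* (uniform on the ring, rotated by π/20), plus the uniform
single-illumination validation design q ≡ 1 AU. Source power is shared
across a design and normalised so the *per-design* maximum nodal fluence at
the prior-mean parameters equals 1 AU — the per-design reading guarantees
no single illumination exceeds the safety ceiling.

**Acoustics.** With a homogeneous lossless medium and ideal point
transducers, the data function is the circular Radon transform of h:
arcs of radius c₀t (c₀ = 1500 m/s) about each transducer, clipped to Ω.
The operator is assembled once per mesh/geometry as an explicit sparse
matrix by fixed-step midpoint quadrature along each arc (step = 1/4 of the
minimum element edge by default; coarser-than-element steps are rejected)
with barycentric interpolation; the adjoint is the exact transpose, which
is what makes the likelihood score exactly adjoint-consistent. The study
geometry uses 360 transducers on a 6 cm ring and 184 samples at 2×10⁻⁷ s
(K = 66 240). The time origin is not dictated by those counts alone; the
package sets t₀ = (6 cm − 5 cm)/c₀ so the arcs sweep the 1–6.5 cm radii
that intersect the object, and exposes t₀ as configuration. The
pressure-time reweighting p = (1/4πc₀²) ∂_t(d/t) is a fixed invertible map
and is deliberately not applied: the pipeline works with d directly.

**Noise and likelihood.** Measurements add i.i.d. Gaussian noise,
Σ_z = σ²I with σ² = 10⁻³ by default. The log-likelihood over I
illuminations is −(1/2σ²) Σᵢ ‖H hᵢ − dᵢ‖² with additive constants dropped.

## Prior

The latents m = (m₁, m₂) carry log-deviations of absorption and reduced
scattering from the references μ̄_a = e⁻² cm⁻¹ and μ̄_s′ = 10 cm⁻¹, with a
block-diagonal Gaussian prior. Each block has covariance C = A⁻² with
A = γ(−Δ) + δ·Id — the SPDE form of a Matérn field with ν = 1 in 2D, which
is trace-class and samples cheaply via C^{1/2} = A⁻¹. Discretely
C = A⁻¹ M A⁻¹ (A the assembled operator, M the consistent mass matrix), so
applying A⁻¹ to white noise with covariance M — drawn exactly by
element-level square roots of the element mass matrices — samples the
field. Per-sample counter-based seed streams make sample *i* reproducible
independently of the batch size.

The operator also carries a Robin boundary term with coefficient
√(γδ)/1.42, the standard empirical choice that suppresses boundary variance
inflation; the variance field's max/min ratio stays below 1.3. Calibration
targets what a practitioner specifies: marginal variance at the domain
centre (0.2 for m₁, 0.05 for m₂) and correlation 0.1 at 5 cm separation. A
closed-form whole-plane initialisation (variance 1/(4πγδ), correlation
(κr)K₁(κr) with κ = √(δ/γ)) is corrected by a fixed-point loop on the
quantities *measured from the assembled operator* (variance tolerance 0.1%,
correlation tolerance 5×10⁻⁴), so the discrete operator — boundary effects
included — meets the targets, not just its continuum idealisation. Note the
5 cm probe lies on the boundary of the 5 cm disk; calibrating on the
measured discrete quantities absorbs that.

The precision applies as C⁻¹ = A M⁻¹ A with a consistent-mass direct solve
(exactness over speed at these sizes). "Pointwise prior variance uniformly
0.2" is interpreted as the Robin-corrected approximately uniform field with
the centre value pinned, the 1.3 max/min ratio serving as the uniformity
check.

## Bound pipeline

The Bayesian information decomposes as J_m = J_P + J_D with J_P = C⁻¹
(Gaussian prior) and J_D estimated by the outer-product average of
likelihood scores at N_s i.i.d. joint draws (prior sample, then data
simulation). The score is computed by the adjoint method: one extra solve
of the self-adjoint diffusion operator per illumination, sharing the
forward factorisation. Rather than discretising continuum adjoint
expressions, the implementation differentiates the discrete objective
exactly (Lagrangian of the algebraic system), with derivative tensors of
the P1 mass/stiffness forms assembled element-wise; correctness is enforced
by a mandatory central-finite-difference contract, which the exact discrete
adjoint passes at ~10⁻⁸ relative (tolerance 10⁻⁵). Gradients are Euclidean
in the nodal coefficients; mass weighting enters only through the design
metric, mirroring the discretise-then-bound structure.

J_D is stored dense and accumulated from a score matrix (n × N_s), which
also yields half-sample estimates for error intervals. J_m = C⁻¹ + J_D is
SPD by construction and inverted by Cholesky *without* regularisation — a
failure there signals an upstream bug and should not be papered over. The
m₁ block of V_m = J_m⁻¹ is the post-marginalised bound (nuisance effects
remain inside it); block ordering is fixed as [m₁; m₂].

The change of variable to μ_a = μ̄_a e^{m₁} uses the diagonal congruence
Ĉᵀ V̂_{m₁} Ĉ with Ĉ_ii = E[μ̄_a e^{m₁,i}]: Monte-Carlo over prior samples by
default (5000 draws at full scale), or the closed-form lognormal mean
μ̄_a e^{var_i/2} from the nodal marginal variances; the two agree to MC
error and are cross-checked in the tests. For the prior-only bound this
congruence gives tr_M = μ̄_a² e^{v} v ·|Ω| (v = 0.2), i.e. ≈ 0.351 — the
linearisation of the bound, not the full lognormal variance
μ̄_a² e^{v}(e^{v}−1)·|Ω| ≈ 0.389; the tests assert the formula the bound
actually computes.

Design schemes are compared by the mass-weighted trace tr_M(V̂_{μ_a}) — a
Bayesian A-optimality criterion whose mass weighting makes the discrete
trace consistent with the integrated pointwise bound in the function-space
limit. Pointwise maps are the nodal diagonals of the relevant blocks;
scalar metrics are exact weighted traces (tr(MX), not lumped diagonals).
A ranking is declared only when half-sample intervals are disjoint.

**Estimator bias at small N_s.** V̂ = (C⁻¹ + Ĵ_D)⁻¹ is convex in Ĵ_D, so
finite-sample estimates are biased upward (Jensen); the bias shrinks as
N_s grows. This matters when comparing the bound to an empirical MSE at
small sample counts and is why the information-inequality test uses N_s
well above the latent dimension.

## MAP validation

The validating estimator minimises the negative log-posterior by inexact
Newton-CG: Gauss-Newton Hessian actions (drop second-order PDE terms; PSD,
matrix-free via one incremental forward and one incremental adjoint solve
per product, reusing the factorisation), Eisenstat–Walker choice-2 forcing
with the standard safeguard, a Steihaug-style nonpositive-curvature exit in
the CG loop (inactive for Gauss-Newton but kept for safety), and Armijo
backtracking. The initial iterate is the prior mean. Gauss-Newton suffices
for a validator because the validation quantities are properties of the
minimiser, not of the optimisation path; a full-Newton mode is left as an
extension point. Expected errors are Monte-Carlo averages over joint draws
with per-trial seed streams; the reported scalars are exact mass-weighted
quadratic errors E[eᵀMe] (failed trials are excluded and counted; more than
1% failures aborts).

## Problem sizes used by the shipped tests

Routine tests run on coarse meshes (element diameter 0.5–0.85 cm, ~100–750
nodes) with reduced acoustic sampling (24–60 transducers, 32–64 times);
the analytic PDE/Radon oracles and the prior-calibration checks run on the
study-scale mesh. The information-inequality and design-ranking checks use
the study-2/3 presets at reduced size — mesh diameter 0.85 cm, 40
transducers × 48 times, N_s = 2000 bound samples, 80 MAP solves per scheme
— chosen so the whole pipeline (including ~160 nonlinear reconstructions)
completes in minutes on one CPU while keeping N_s far above the latent
dimension, where the inequality and the ranking hold with clear margins.
The published full-scale configuration (study mesh, 360 × 184 data,
N_s = 5000, 10⁴ reconstructions) is exposed as `study_config(n, "full")`;
its bound stage is a workstation-hours computation and its MSE stage a
cluster computation, so the shipped tests exercise the identical code path
at reduced size rather than reproducing the full-scale table values.

## What the synthetic data does and does not show

All inputs are generated internally: parameter fields from the calibrated
prior and measurements from the forward model plus Gaussian noise, exactly
the regime in which the Bayesian CRB's expectations are defined. Passing
tests therefore establish the *internal* consistency and calibration of the
pipeline (oracle agreement, exact adjoints, the information inequality,
reproducible rankings) — not that the diffusion approximation, the
idealised point-transducer CRT, the lossless homogeneous acoustics, Γ ≡ 1,
or the log-Gaussian Matérn prior describe any particular physical system.
Real tissue exhibits vascular structure, absorption–scattering correlation,
acoustic heterogeneity and transducer response that this virtual system
deliberately omits.

## Known limitations

* 2D geometry only; no radiative-transfer or Monte-Carlo photon transport;
  no refractive-index-mismatch boundary conditions.
* No transducer impulse response, finite apertures, or acoustic
  attenuation; the CRT time window covers arc radii 1–6.5 cm, which spans
  the object but not the full 1–11 cm transducer-to-point range.
* Per-sample relative accuracy of the CRT degrades near grazing incidence
  (arcs tangent to a feature), an intrinsic resolution limit of any
  mesh-based discretisation; aggregate accuracy is unaffected.
* The MAP problem is non-convex: the solver finds local minimisers, and
  the reported MSEs are conditional on the solver's standard settings
  (stopping tolerances are printed with each run's provenance record).
* Free optimisation over continuous source placement is out of scope: the
  pipeline ranks named design schemes.
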