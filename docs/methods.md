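# Methods

## Model

A fluorescently tagged protein A binds reversibly to an abundant,
homogeneously distributed partner B.  Because [B] is unchanged by
photobleaching, the kinetics are pseudo-first-order with association rate
k_on = k̄_on·[B] and dissociation rate k_off.  Writing u(r, t) and v(r, t)
for the fluorescent free and bound concentrations (radially symmetric
geometry, fluorescence normalised so the pre-bleach total is 1), the
post-bleach dynamics are

    ∂u/∂t = D_u ∇²u − k_on u + k_off v − α I(r,t) u
    ∂v/∂t = D_v ∇²v + k_on u − k_off v − α I(r,t) v

with ∇² the radial Laplacian, I(r, t) a top-hat laser profile over the
bleach disk of radius r_n active during the bleach phase, and α the
photosensitivity.  The observable is the total fluorescence w = u + v; a
recovery curve is its area average over the bleach region of interest.

Three dimensionless groups control the dynamics and, with them, which of
the four unknowns θ = (D_u, D_v, k_on, k_off) the data can determine:

| group | definition | meaning |
|---|---|---|
| η | D_u/(k_on r_n²) | free-diffusion rate across the ROI vs binding rate |
| κ | k_off/k_on | equilibrium constant ratio (u_eq = κ/(1+κ)) |
| δ | D_v/D_u | bound-state mobility |

Asymptotic regimes implemented in `frapkit.analytic`:

- **Rapid equilibration (η ≫ 1).** Diffusion through the ROI is fast;
  F(t) = u_eq F_S(r_n²/2D_u t) + v_eq(1 − e^{−k_off t}[1 − F_S(r_n²/2D_v t)]),
  where F_S(z) = e^{−z}(I₀(z) + I₁(z)) is the single-species pure-diffusion
  recovery function.  With D_v = 0 and an unresolved diffusion phase this
  degenerates to the classical exponential F = 1 − v_eq e^{−k_off t}, in
  which D_u is structurally absent; a first-order correction in 1/η
  restores weak D_u dependence.
- **Slow equilibration (η ≪ 1).** Binding equilibrates locally before
  transport matters; w diffuses with the effective diffusivity
  D_eff = u_eq D_u + v_eq D_v = (k_on D_v + k_off D_u)/(k_on + k_off), and
  only that combination is identifiable.
- **Rate asymmetry (κ ≫ 1 or κ ≪ 1).** Nearly all material is free
  (respectively bound) and the recovery is single-species diffusion with
  D_u (respectively D_v).

The first-order correction formula is implemented exactly as it circulates
in the literature; note its prefactor k_on r_n/(3 D_u) carries residual
units of 1/μm, so the formula breaks the diffusive (D, r_n²) scaling
invariance and is excluded from unit-scaling property tests.

Inverting the effective diffusivity for the rate ratio gives
κ = (D_eff − D_v)/(D_u − D_eff); `kappa_from_deff` implements this
self-consistent form (substituting back reproduces D_eff bit-for-bit) and
offers the reciprocal form, which also circulates, behind an explicit
`as_printed` flag for audit only.

## Forward solver

The disk 0 ≤ r ≤ R with zero-flux walls stands in for the far field;
default R = 20 r_n makes the bleached mass fraction (r_n/R)² = 0.25%,
which bounds the equilibrium offset of the finite domain.  The radial
Laplacian is discretised with central differences on a uniform grid
including r = 0 (where l'Hôpital gives ∇²u|₀ = 2∂²u/∂r²), with ghost-node
closures for the symmetry and zero-flux boundaries; default Δr = r_n/20.

Two backends share this discretisation:

- **`eig` (default).** The discrete radial Laplacian L satisfies detailed
  balance with respect to annulus weights (m₀ = Δr/8, m_j = r_j,
  m_N = (R − Δr/2)/2), so S = M^{1/2} L M^{−1/2} is symmetric tridiagonal;
  scaling the species by √u_eq and √v_eq symmetrises the kinetic coupling
  to √(k_on k_off)·identity.  Because the coupling is then proportional to
  the identity, the full 2n×2n generator block-diagonalises in the
  eigenbasis of S into n independent 2×2 symmetric blocks.  The
  eigendecomposition of S is computed once per grid and cached; each
  parameter evaluation costs one analytic 2×2 eigenproblem per mode plus
  exponentials.  Propagation is exact in time — the only numerical error
  is spatial discretisation — and is unconditionally stable, so the
  stiffest parameter draws (k_on ~ 10⁵/s in the slow-equilibration window)
  cost the same as the mildest.  Modal branches whose exponential has
  decayed below 10⁻¹⁷ by the first frame are dropped.
- **`lsoda`.** Method-of-lines integration with a stiff solver and a
  banded (two sub/super-diagonal, interleaved-species) Jacobian, relative
  tolerance 10⁻⁶ and absolute 10⁻⁹.  This is the classical approach; it
  also integrates the time-gated bleach phase, whose sink term the cached
  eigenbasis does not diagonalise, and serves as an independent
  cross-check of the eigensolver (the two agree to ~10⁻⁷ sup-norm on
  benchmark curves; a property test enforces 10⁻⁴).

The instantaneous-bleach initial state u = u_eq H(r − r_n) is represented
by its annular cell averages (a second-order treatment of the sharp edge;
plain nodal sampling costs one order).  ROI readout uses trapezoidal
annular weights ∝ 2π r_j Δr over r_j ≤ r_n, renormalised so w ≡ 1 maps to
F = 1 exactly.  Against closed-form oracles the defaults deliver: pure
diffusion vs the Soumpasis curve ≤ 2.1×10⁻³ sup-norm; rapid- and
slow-equilibration limits ≤ 2.5×10⁻³; mass conservation ≤ 5×10⁻⁷
relative; halving Δr moves the default recovery curve by < 10⁻³.

## Synthetic-experiment protocol

The generator draws D_u ~ U(0, 50] μm²/s (biologically plausible
mobilities), log₁₀η ~ U(−3, 3), k_on = D_u/(r_n²η), κ = 4^κ̃ with
κ̃ ~ U(−1, 1), k_off = κ k_on, δ ~ U(0, 0.1), D_v = δ D_u.  Regime studies
restrict the η window ([1, 3] decades = rapid, (−1, 1) intermediate,
[−3, −1] slow) or replace the κ law with a log₁₀ window for the
rate-asymmetry studies.  Data are noiseless by default (additive Gaussian
noise with recorded σ_i is available); initial guesses are either
"precise" (each component inflated by an independent U(0, 50%) factor) or
an independent regime-restricted redraw.  The standard acquisition is
1024 frames; the benchmark design spans 15 s (Δt ≈ 1.46×10⁻² s), and the
"standard"/"high" frame-rate presets use Δt = 10⁻² s and 10⁻⁴ s with the
frame count governing the duration.

What the generator does **not** emulate: photon/detector noise statistics,
bleaching during acquisition, diffraction-limited bleach-edge blur,
anisotropic or Gaussian laser profiles, cell boundaries and heterogeneous
binding-site density.  Passing benchmarks therefore demonstrate the
identifiability structure of the idealised model, not robustness to
real-microscope artefacts; the bleach-phase mode (top-hat sink of rate
10/s for 1 s by default, both values conventions rather than measured) is
provided to probe sensitivity to non-ideal initial conditions.

## Fitting

Objectives are residual sums of squares over recovery curves
(Σ_k Σ_i (F_data − F_model)², optionally weighted by 1/2σ_i²) or spatial
fields (Σ_k Σ_i Σ_j over frames and radial bins), summed over experiments
with different bleach radii.  Model output always comes from the
numerical simulator at the data's own discretisation; the closed-form
curves are available as an explicit fast backend but never silently.

Minimisation is Nelder–Mead in log₁₀-parameter space: positivity is
automatic, interior optima are unmoved, and scale differences between
rates and diffusivities disappear.  The initial simplex perturbs each
coordinate by +0.05 decades (the scipy default simplex degenerates near
log θ = 0).  Defaults: termination at 10⁻⁶ simplex size (10⁻⁵ in batch
studies) and 10⁻¹⁰–10⁻¹⁴ objective change, 800-evaluation cap in batch
studies (2000 for one-off fits), two restarts from a ±0.1-decade
perturbation on non-convergence.  Box-constrained fits pass bounds to the
optimiser (clipping rule); an estimate within relative 10⁻³ of a bound
raises its `at_bound` flag.

Errors are scored as proportional estimation errors |θ̂ − θ|/θ per
parameter, plus the derived D_eff combination; f(μ) is the fraction of
instances below threshold μ (default 1%).  A zero true D_v (δ = 0 has
positive density in the sampler) is scored as |D̂_v|/D_u instead of the
undefined proportional error.  Failed instances count against every
success fraction.  Batch studies default to 16–64 instances (the
full-scale references used 1024, or 128 per bin); every reported fraction
carries its 95% binomial half-width 1.96·√(p(1−p)/n) so reduced-scale
results can be read honestly.

## Identifiability diagnostics

For model-generated data the Fisher information matrix reduces to
I_μν = Σ_i σ_i⁻² (∂F_i/∂θ_μ)(∂F_i/∂θ_ν).  Sensitivities are central
differences with multiplicative steps 10^±10⁻⁴ (a relative step in
log-parameter space; parameters exactly zero fall back to a one-sided
absolute step).  A spectrum with λ_min/λ_max below 10⁻⁶ (configurable) is
flagged sloppy and the near-null eigenvector names the locally
inestimable parameter combination.

The default setting for the frame-interval spectrum study is D_u = 20
μm²/s, κ = 0.5, δ = 0.01, r_n = 0.5 μm.  δ is small but strictly positive
because the rapid-equilibration formula behaves like √D_v near D_v = 0,
so at δ = 0 the D_v derivative is singular and any finite-difference
column is a step-size artefact.  At this setting, one eigenvalue (the D_u
direction) sits ≥ 4 decades below the other three whenever the frame
interval is ≥ 2 r_n²/D_u, and the gap narrows monotonically as Δt
decreases — the spectral statement of "D_u is estimable only if the
diffusion phase is temporally resolved".

The tractability report evaluates κ within [10⁻⁰·⁹, 10⁰·⁵³] (empirically
measured regime boundaries), δ ≤ 0.1, and the mode-specific experimental
ratios (ROI ratio and Δt·D_u/r_n² for recovery curves; pixel-scale and
field-of-view ratios for spatial data), reading "≪/≫" as a ×10
separation.  All thresholds are configurable and reported next to the raw
ratios — the verdicts are order-of-magnitude guidance, not sharp tests,
and should always be read with the ratios themselves.

## Regime identification

Candidate regimes are boxes in (log₁₀η, log₁₀κ): rapid equilibration
η > 10¹·⁷, intermediate 10⁰·⁴ ≤ η ≤ 10¹·⁷, slow equilibration η < 10⁰·⁴,
and for the rate-asymmetry study κ > 10⁰·⁵³ (U), κ < 10⁻⁰·⁹ (V) and the
κ-windowed rapid box.  Each candidate is fitted with (η, κ) constrained
to its box — the constraints are natural in dimensionless space
(D_u, δ, η, κ), with the smallest bleach radius anchoring η when several
radii are fitted jointly — plus a one-parameter pure-diffusion fit (the
k_on = k_off = 0 limit of the same simulator, seeded by a coarse log-grid
scan so it needs no user guess).  Fits are scored with
AIC = 2N_param + N_data ln φ (φ floored at 10⁻³⁰ for noiseless
self-fits); a candidate whose constrained optimum is pinned (relative
10⁻³) to a boundary *between* regimes is rejected — the optimiser
straining against the box wall means the optimum lies outside — and the
smallest AIC among survivors wins, ties within 10⁻⁶ going to fewer
parameters.  Because a simplex clipped against a bound can stall short of
an interior optimum sitting just inside the box (data whose true η lies
within a few percent of a regime edge), a fit that finishes pinned is
restarted once from a point pulled 0.1 decades off every pinned wall and
the better result kept; a genuinely exterior optimum drives the restart
straight back to the wall, so the rejection rule is unaffected where it
matters.  A pure-diffusion win labels the data "diffusive"; with
independently measured D_u and D_v, `classify_diffusive` then separates
κ ≫ 1 (D ≈ D_u), κ ≪ 1 (D ≈ D_v) and slow equilibration
(D_v < D < D_u ⇒ D = D_eff, κ recovered by inversion).  The slow and
diffusive candidates genuinely overlap — slow-equilibration data *are*
effectively diffusive — so the one-parameter model occasionally wins
there by parsimony; this is expected behaviour, not a defect.

## Problem sizes and defaults

Benchmarks in the test suite run at n = 16 instances (n = 64 for the
recovery-curve fraction study), 1024-frame acquisitions, and the default
grid (401 radial nodes); these sizes were chosen so the whole suite runs
on a laptop-class single core while keeping binomial uncertainty small
enough to compare against the full-scale reference fractions.  Full-scale
runs (n = 1024/128) are a `StudySpec(n_run=...)` away.

## Known limitations

- The closed-form curves assume an infinite domain and instantaneous
  bleaching; comparisons with the finite-disk simulator inherit a
  ~(r_n/R)² equilibrium offset.
- Boundary rejection uses the fitted dimensionless point only; it does
  not inspect the objective's curvature at the wall.
- The bleach-phase parameters (α·I amplitude, duration) are conventions;
  no attempt is made to calibrate them to a physical laser.
- `estimation_error` and the batch metrics presume strictly positive true
  parameters except for the documented D_v = 0 case.
- No uncertainty quantification beyond the Fisher spectrum (no profile
  likelihoods, no posterior sampling).
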