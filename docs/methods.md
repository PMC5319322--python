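# Methods

## Model and assumptions

`avmech` implements a transversely isotropic viscoelastic constitutive
model for planar collagenous tissue with one preferred fibre direction,
developed for the aortic-valve leaflet. The key assumptions are:

- **Incompressibility.** det F = 1 throughout; the indeterminate pressure
  p is eliminated analytically through traction-free boundary conditions
  (σ₂₂ = σ₃₃ = 0 in uniaxial circumferential loading, σ₁₁ = σ₃₃ = 0
  radially, σ₃₃ = 0 for the thin-membrane biaxial forms). Carrying p
  numerically instead would only add round-off.
- **Pure homogeneous deformation.** All factory-built states are
  diagonal (F = diag(λ₁, λ₂, λ₃)), which is what uniaxial and biaxial
  tensile protocols impose. The invariant, derivative and stress routines
  nevertheless accept arbitrary symmetric C and Ċ so the general tensor
  algebra is testable; shear-controlled loading and through-thickness
  analysis are out of scope.
- **Transverse isotropy.** One fibre family M = [cos φ, sin φ, 0]; the
  energy depends on deformation through I₁–I₅ and J₁–J₁₂. Fibre
  dispersion is not modelled.
- **Explicit rate dependence, monotonic loading.** The viscous potential
  is an algebraic function of Ċ, so the model targets constant-rate ramp
  (monotonic proportional) loading. It is not a hereditary-integral
  formulation and is not suitable for predicting stress relaxation or
  creep; no such prediction is exposed.
- **Fibre compression switch.** Collagen fibres buckle in compression.
  Coefficient evaluation zeroes the fibre terms (We₄, We₅, Wv₄, Wv₅,
  Wv₁₀, Wv₁₁) when I₄ ≤ 1, or unconditionally under the explicit
  radial-loading convention flag. The radial closed form therefore
  contains no k₁, k₂ or η₂.

## Angular-momentum constraint

For this invariant family the Cauchy stress σ = FSFᵀ is **not**
automatically symmetric: symmetry holds iff
(Wv)₁₂ = −(Wv)₁₀/(λ₁² + λ₂²). `cauchy_general` enforces this by
overwriting (Wv)₁₂ before assembly (the default for all public stress
evaluation); the unconstrained assembly is retained behind a flag solely
so the defect — λ₁λ₂(λ₂²−λ₁²) sin 2φ [(Wv)₁₀ + (λ₁²+λ₂²)(Wv)₁₂] — can be
measured and tested. For the package's chosen Wv, (Wv)₁₀ = (Wv)₁₂ = 0 and
the constraint is vacuous.

A related subtlety: for the fibre–rate invariants J₁₀–J₁₂ the
unconstrained matrix-calculus gradients (what entry-wise finite
differencing recovers, e.g. ∂J₁₀/∂Ċ = CM⊗M) differ by a transpose or an
operand ordering from the forms used in the constitutive stress assembly
(e.g. (M⊗M)C), which correspond to contraction with symmetric rate
variations. `kinematics.invariant_derivatives` returns the former, the
stress module assembles the latter; the two coincide for every on-axis
fibre configuration (φ ∈ {0, π/2}) and for all states the model is used
with. Both are pinned by tests (finite-difference oracle on one side, an
independent component-wise expansion of the diagonal-state Cauchy stress
on the other).

## Parameters

| parameter | meaning | units | reference value |
|---|---|---|---|
| α | isotropic matrix stress scale | MPa | 0.0217 |
| β | matrix exponential stiffening | – | 1.389 |
| k₁ | fibre stress scale | MPa | 0.5853 |
| k₂ | fibre exponential stiffening | – | 0.4250 |
| η₁ | matrix (GAG) viscosity, shared across directions, per rate | MPa·s | 6.082 / 1.821 / 0.3771 at λ̇ = 0.01 / 0.1 / 0.5 s⁻¹ |
| η₂ | fibre-kinematics viscosity, circumferential only, per rate | MPa·s | 273.2 / 58.75 / 16.68 at the same rates |

All elastic parameters are strictly positive (also required by
convexity); viscosities are non-negative. η is dimensionally a stress
times time: η·λ̇ must be a stress, so the package uses MPa·s throughout
(reference tabulations sometimes label these values "MPa s⁻¹"; the
numbers are used as printed, only the unit reading differs).

The reference set ships as `REFERENCE_ELASTIC` / `REFERENCE_VISCOUS` and
is the default ground truth of the synthetic generator.

## Estimation procedure

Two phases, mirroring the elastic/viscous split of the model:

1. **Elastic baseline.** A tensile ramp slower than the tissue's slow
   relaxation leaves no viscous stress to measure: 99% of relaxation
   fades within 5τ, so a ramp from λ = 1 to the failure stretch over 5τ,
   i.e. λ̇ = (λ_fail − 1)/(5τ), is the baseline rate
   (`elastic_baseline_rate`; 0.0011 s⁻¹ circumferentially with τ = 81.14 s,
   0.0055 s⁻¹ radially with τ = 32.11 s — hence 0.001 s⁻¹ as the
   experimental baseline). Phase 1 fits the purely elastic terms to the
   baseline curve pair with α, β shared between directions; the radial
   curve alone pins the matrix pair, the circumferential curve adds
   k₁, k₂.
2. **Per-rate viscosities.** With the elastic set frozen, (η₁, η₂) are
   fitted to each rate's curve pair, η₁ shared across directions, η₂
   identified from the circumferential curve only (it does not appear in
   the radial model; a radial-only fit leaves it at its initializer with
   zero gradient).

Both phases use Levenberg–Marquardt on stacked per-point residuals
(`scipy.optimize.least_squares`, `method="lm"`). LM is unconstrained, so
parameters are fitted in log-space, which enforces positivity exactly.
Initial guesses are α = 0.01 MPa, β = 1, k₁ = 0.1 MPa, k₂ = 0.1, η = 1;
five starts (the canonical one plus four with seeded log-normal jitter,
scale 0.5) guard against local minima and the lowest-SSE solution wins.
Residuals are equally weighted per point by default; per-curve
inverse-variance weighting is a config option. Every fit records per-curve
R² and a convexity verdict of the resulting energy over the fitted stretch
range. Non-finite residuals from wild jittered starts are clamped to a
large finite value so LM backtracks instead of aborting.

## Convexity verification

Strict local convexity is audited through the 2×2 Hessian of W in
(λ₁, λ₂) with λ₃ = 1/(λ₁λ₂) substituted. Four redundant conditions are
evaluated independently at every point of a 51×51 grid (default domain
[1, λ_fail]²): positive diagonal entries, positive determinant, positive
eigenvalues. The elastic Hessian is analytic (verified against central
finite differences to 1e−5 relative); the total-energy Hessian freezes
the in-plane stretch rates at supplied values, derives the thickness rate
from the isochoric condition, and differentiates numerically (central
differences, step 1e−4). Freezing λ̇ covers the reading in which the
audited W is the total energy at a given test rate; the elastic-only
audit is always available separately. Two numerical choices matter:

- the eigenvalue check tolerates a smallest eigenvalue down to
  −1e−10·(|h₁₁|+|h₂₂|) to absorb round-off at the undeformed corner;
- the energy surface being audited applies the fibre family per direction
  convention (on or off for the whole surface), not the pointwise I₄
  switch — the viscous fibre term does not vanish continuously at I₄ = 1,
  so a pointwise switch would make W discontinuous across the λ = 1 grid
  edge and corrupt finite differences there. On the audit domain
  (stretches ≥ 1) the two conventions describe the same physics.

The verdict for the reference parameters is grid-refinement stable from
25² to 101² points.

## Viscosity–rate power law

η(λ̇) = a·λ̇ᵇ is fitted by ordinary least squares on (ln λ̇, ln η). This
choice reproduces the reference coefficients (a = 0.275, b = −0.698 for
η₁; a = 10.63, b = −0.711 for η₂); an unweighted nonlinear allometric fit
is dominated by the large slow-rate viscosities and lands on a materially
different exponent (≈ −0.56 for η₁), so it is offered only behind
`fit_space="linear"`. Extrapolations: η₁ = 0.145, η₂ = 5.54 MPa·s at the
physiological 2.5 s⁻¹; 0.845 and 33.39 MPa·s at the 0.2 s⁻¹ validation
rate. The three-point fits are unbiased in log space by construction, but
not tight: the η₁ point at 0.1 s⁻¹ sits 25% off its own best-fit line, so
extrapolated viscosities inherit that order of uncertainty.

## Synthetic data generator

The generator emulates the uniaxial protocol: curve pairs (circumferential
λ ∈ [1, 1.46], radial λ ∈ [1, 1.89], 40 uniform points) at rates 0.001,
0.01, 0.1, 0.2 and 0.5 s⁻¹, three replicates, reference ground truth.
The 0.001 s⁻¹ curves are the elastic baseline and are generated without a
viscous term, consistent with how Phase 1 treats them; the 0.2 s⁻¹
viscosities, which are not part of the calibrated set, are filled in from
the fitted power law — the same construction used to validate predictions
at that rate. Noise is multiplicative Gaussian (σ·(1+ε), ε ~ N(0, 0.02²)
by default, clipped at zero) because stresses span orders of magnitude
along a curve, making a constant relative error the realistic model;
replicates are independent noise draws. Everything is deterministic under
a seed.

What the generator does **not** emulate: inter-specimen parameter
variability (an optional construction, not enabled by default), gripping
and end-effect artefacts known to affect radial strips, rupture behaviour
beyond truncation at the failure stretch, and any misspecification of the
constitutive form itself — the synthetic curves are draws from the model
being fitted. Passing recovery tests therefore demonstrate that the
estimation pipeline is correct and well-conditioned at realistic noise,
not that the model fits real valve tissue; that case rests on the
published experimental fits.

`recovery_study` quantifies the pipeline: noise-free recovery is exact to
optimizer tolerance (≤ 1e−6 relative); at 2% noise, 20 seeds, four rates,
every parameter's median relative error stays below 3% (bound asserted at
10%).

## Problem sizes

Defaults were chosen so every routine runs in seconds on one CPU: 40
points per curve, 51×51 convexity grids, 50 random states for the
closed-form/tensor equivalence check, 20 seeds for the recovery study.
All are arguments, not constants.

## Known limitations

- Relaxation/creep prediction is out of scope by model class.
- The ∂J₃/∂Ċ (det Ċ) derivative is undefined for singular rate tensors;
  it is only evaluated when a constitutive coefficient actually multiplies
  it, and raises otherwise.
- The printed uniaxial (Wv)₁₀ term is encoded as derived from the general
  symmetric assembly under uniaxial kinematics; for the package's chosen
  potentials the coefficient is identically zero, so no numerical path
  depends on it.
- Parameter identifiability degrades if the radial curve is absent
  (α, β then lean on the circumferential matrix term, which the fibre
  term dominates) — the pipeline requires the curve pair in Phase 1.
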