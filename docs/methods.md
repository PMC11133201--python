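# Methods

## Model class

All computation assumes a linear recursive latent-variable system

    η_endo = B η_endo + Γ η_exo + ζ,      x = Λ η + ε,

with zero means and no intercepts, a reflective measurement model in
which every indicator loads on exactly one latent variable, mutually
uncorrelated measurement errors (Θ diagonal, entries ≥ 0), symmetric
positive-definite covariance Σ among the exogenous latents, disturbances
ζ uncorrelated with predictors and with ε, and a strictly acyclic
structural graph (so I − B is unit-triangular and invertible).
Correlated measurement errors, feedback loops, formative measurement,
mean structures and categorical indicators are rejected at validation:
the bias algebra below requires Σ_δ diagonal, and all benchmark models
are recursive.  Indicator order is everywhere the concatenation of blocks
in declared latent order, which makes CSV round-trips unambiguous.

## Attenuation and the bias matrix

A factor-wise composite `η̃ = w'x` decomposes exactly as
`η̃ = qη + δ` with `q = w'λ` and `Var(δ) = w'Θw`.  For one structural
equation, OLS on composites converges to `Mγ` with
`M = (QΣQ + Σ_δ)⁻¹QΣ·q_dep`.  Three structural facts are used heavily
and are enforced by property tests:

* zeros of `Mγ` are invariant to positive rescaling of any composite;
* `M` is diagonal — and the bias correctable by the diagonal matrix
  `D = diag(1/M_ii)` — exactly when predictors are uncorrelated or the
  equation has a single predictor (tolerance for "diagonal": 1e-8,
  appropriate for population-exact algebra in floating point);
* as Θ → 0 with `w'λ = 1`, `M → I`.

For equations whose predictors include endogenous latents, the same
formula is applied per equation over the causal ordering, with Σ taken
from the model-implied latent covariance matrix.  This per-equation
extension is the package's own reading for multi-equation systems; it is
exact because in a recursive system ζ is uncorrelated with the equation's
predictors, so `Cov(η_pred, η_dep) = Σγ` still holds.  The degeneracy
solver picks `γ` with `(Mγ)_target = 0` and `γ_target` fixed, using the
minimum-norm completion of the single homogeneous row condition; `q_dep`
is a positive scalar and is dropped from that condition since it cannot
move zeros.

## Composite weighting schemes

All four schemes are factor-wise (weights supported on the latent's own
block), moment-based (they consume a covariance matrix, never raw data),
and finish by rescaling each composite to unit variance under the input
matrix — a convention that leaves z and τ unchanged and pins down scale.
Sign indeterminacy is resolved by flipping any weight vector whose summed
covariance with its own block is negative.

* **EWC**: equal weights within a block (a raw 1/m_b variant is exposed
  for analytic work where `q = 1` is convenient).
* **BFS**: `w ∝ Θ̂⁻¹λ̂(λ̂'Θ̂⁻¹λ̂)⁻¹` from CB-SEM estimates; requires
  strictly positive estimated error variances.
* **PLS Mode A / Mode B**: Lohmöller-style iteration on the covariance
  matrix; inner proxies use the factorial scheme by default (centroid and
  path schemes selectable), outer updates are covariances with the inner
  proxy (Mode A) or block-regression coefficients on it (Mode B);
  convergence when the maximum absolute weight change drops below 1e-10
  (default), 300 iterations maximum, equal-weight initialization.
  Non-convergence is flagged on the result, not raised.
* **Mode B_A**: the Mode-A fixed point finished with one Mode-B outer
  step; the step count is configurable because the hybrid's definition
  admits variants.

With parallel measures (equal loadings and error variances within each
block) all four schemes coincide exactly up to scale — the benchmark
models exploit this, so every composite result there is scheme-independent.

## NML estimation and scaling methods

CB-SEM minimizes `F_ML = log|Σ(θ)| + tr(SΣ(θ)⁻¹) − log|S| − p` with the
sample covariance computed with divisor n−1 and `χ² = (n−1)·F_ML`.  Two
identification devices are implemented:

* **marker**: exogenous latent variances fixed to 1, first loading of
  each endogenous latent fixed to 1, disturbance variances free;
* **standardized**: every latent variance equal to 1, imposed by
  substitution — each disturbance variance is replaced by one minus the
  variance its equation explains under the current coefficients, so the
  constraint holds exactly at every iterate and the parameter vector
  stays unconstrained.

Both parameterizations cover the same implied-covariance manifold with
the same free-parameter count, hence identical minimized discrepancy and
df; the package asserts this to 1e-6 on every comparison.  Optimization
is BFGS with derivatives by complex-step differentiation of `F_ML`
(machine-precision, no cancellation; step 1e-60), gradient tolerance
1e-9, up to 500 iterations, with a polish pass and a fallback start if
the data-driven start fails.  Starting values come from equal-weight
composite regressions (loadings from indicator–composite covariances,
paths from composite-level OLS), falling back to 0.5 for loadings and 0
for paths.  Non-PD Σ(θ) during the search is handled by a large penalty
value.  Negative variance estimates (Heywood cases) are flagged on the
fit and never truncated.

Standard errors use the expected (Fisher) information
`I_ij = tr(Σ⁻¹∂Σ_iΣ⁻¹∂Σ_j)/2` by default, `se = sqrt(diag(I⁻¹)/(n−1))`,
with the observed information (finite-difference Hessian of `F_ML/2`)
as an option; the two agree asymptotically and are tested to 5% at
n = 5000.  Expected information is the default because it matches the
mainstream SEM software convention.  A near-singular information matrix
raises an error naming the parameters aligned with the null direction.

## Path OLS, z, and the signal-to-noise ratio

Composite path equations are estimated from moments:
`γ̂ = C_xx⁻¹C_xy`, residual variance from the Schur complement with the
n−k−1 degrees-of-freedom correction (the uncorrected 1/n variant is a
switch, since reported z-statistics in the literature do not always state
the convention), `se = sqrt(σ̂²·diag(C_xx⁻¹)/(n−1))`-equivalent in moment
form, `z = γ̂/se`, `τ = z/√n`.  Composite scores are treated as observed
data: no correction is attempted for the sampling variability of
estimated weights, matching the practice of the methods being compared.

## Comparison engine and Monte Carlo

The engine fits CB-SEM once per problem (plus a canonical marker-scaled
fit from which Bartlett weights are always computed — this makes the
BFS/EWC/PLS columns bit-identical across CB-SEM scaling choices, as the
theory says they must be), then runs the four composite pipelines and
tabulates z and τ per structural path.  Rank summaries rank |z| per path
(1 = largest) with averaged ranks and fractional extreme counts under
ties, so count rows always sum to the number of paths.  Per-problem
failures are recorded and skipped, never fatal to a batch.

Monte-Carlo studies draw multivariate-normal data through independent
seed-sequence substreams spawned from one master seed (reproducible and
order-independent), apply every method per replication, and test each
path with a two-sided z-test against the standard normal — no
small-sample t refinement, matching the z-statistic framing throughout.
Replications where a method fails are excluded from that method's
proportions and reported as counts; Monte-Carlo standard errors are
`sqrt(p(1−p)/reps_effective)`.

## Benchmark models (what the generator emulates)

* **Counterexample** (`make_counterexample`): two exogenous latents with
  variance 1 and covariance ρ (default −2/3), one endogenous latent,
  three parallel indicators per latent (loadings 1, error variances 1),
  disturbance variance 1; `γ₂` chosen by the degeneracy solver so the
  composite plim of `γ₁` is exactly zero while `γ₁ ≠ 0` (default 0.25,
  which yields `γ₂ = 1`).  With ρ = 0 no degeneracy exists and the
  constructor refuses.
* **Null model** (`make_null_model`): same structure with `γ₁ = 0`; with
  ρ = −2/3 and `γ₂ = 1` the composite plim of the zero path is ≈ −0.126
  on unit-variance composites, the engine of type-I inflation.
* **Mediation model** (`make_mediation_model`): ξ → η1 → η2 with a direct
  path, loadings 0.9/0.8/0.7, error variances 0.5, unit latent variances
  by construction — chosen so the marker and standardized scalings are
  genuinely different parameterizations.
* **Random models** (`make_random_model`): loadings U[0.5, 1], error
  variances U[0.3, 1], random correlation matrix for the exogenous block,
  random recursive structure with coefficients bounded away from zero,
  disturbance variances U[0.3, 1]; deterministic in the seed.

Sampled data are exactly multivariate normal, so passing Monte-Carlo
tests demonstrates behavior under the maintained NML assumptions only;
nothing here speaks to non-normal indicators, misspecified measurement
structure, missing data, or small-sample refinements.  Problem sizes in
the shipped studies (9–15 indicators, n = 300–10 000, up to 1000
replications) were chosen as the smallest sizes at which the asymptotic
identities are numerically clean.

## Known limitations

* No consistent-PLS or attenuation-corrected factor-score regression:
  the package studies uncorrected composite path analysis by design.
* No robust (sandwich) standard errors, M-estimation for non-normal
  data, or missing-data ML.
* The bias algebra is asymptotic; finite-sample bias is only visible
  through the Monte-Carlo engine.
* External covariance matrices can be analyzed through the registry
  format, but none are shipped; all shipped studies are synthetic.
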