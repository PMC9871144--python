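# Methods

## The model

The ex-Gaussian (EG) distribution — the convolution of a Normal(μ, σ²)
"transmission/motor" component and an independent Exponential(mean τ)
"decision" component — is the canonical parametric model for reaction
times (RTs), behavioural and neuronal alike.  Its density and
distribution function are

    f_EG(x) = (1/τ) exp(−(x−μ)/τ + σ²/(2τ²)) Φ(z − σ/τ),
    F_EG(x) = Φ(z) − exp(−(x−μ)/τ + σ²/(2τ²)) Φ(z − σ/τ),   z = (x−μ)/σ,

which is always right-skewed.  The generalised exponential-Gaussian
(GEG) family removes that restriction by exponentiating the EG
distribution function (a fractional order statistic, or Lehmann
alternative):

    F_GEG(x; τ, μ, σ, α) = [F_EG(x; τ, μ, σ)]^α,   α > 0,
    f_GEG(x) = α f_EG(x) [F_EG(x)]^{α−1}.

α is a dimensionless shape exponent: α = 1 recovers the EG exactly;
α < 1 pushes mass left (through symmetric down to negatively skewed
shapes); α > 1 pushes mass right.  In the limit τ → 0 the EG part
collapses onto N(μ, σ²), so the GEG tends to the power-normal (PN)
family, and with α = 1 to the Normal itself.  The inverse risk
(reversed hazard) inherits the clean proportionality
r_GEG = f_GEG/F_GEG = α·r_EG.

Support is the whole real line: RT positivity is a property of data,
not of the family, and no truncation is applied.

## Numerical evaluation

The textbook EG expressions overflow for small τ (the factor
exp(σ²/2τ²) alone).  All kernels therefore work through the Mills-type
ratio R(t) = Φ(t)/φ(t) = √(π/2)·erfcx(−t/√2), using the identity
e^a Φ(b) = φ(z) R(b) (a the exponential prefactor, b = z − σ/τ):

* log f_EG = −log τ − z²/2 − log√(2π) + log R(b) — finite for
  standardized |z| ≤ 40 and σ/τ from 1e−3 to 1e3 and far beyond;
* log F_EG = log φ(z) + log(R(z) − R(b)) for z < 0 — a difference of
  two well-scaled ratios, accurate to full relative precision deep into
  the left tail (needed by the GEG log-likelihood when α < 1);
* for z ≥ 0, F_EG is formed linearly as Φ(z) − exp(a + log Φ(b))
  (exponent clamped at 0), which is exact where F → 1; the subtractive
  Mills form would lose ~eps·z²/2 of absolute log-accuracy there.
  The residual floating-point guard clamps F to [1e−300, 1].

F_GEG = exp(α·log F_EG); survival uses −expm1(·) to keep relative
precision in the right tail.  Quantiles invert log F_EG by bracketed
vectorized bisection on the log-CDF scale (the level u^{1/α} is carried
as log(u)/α, so extreme α cost no precision), with Normal- and
Exponential-tail anchors for the initial bracket; 100 halvings reach
machine precision, far below the 1e−10 contract.  Random generation is
inverse-CDF sampling of uniforms — sampler correctness reduces to
quantile correctness, which the test suite checks by quadrature,
root-finding and Kolmogorov–Smirnov oracles.

## Maximum likelihood and inference

`FamilyModel.fit` maximizes the log-likelihood in the unconstrained
parameterization (log τ, μ, log σ, log α) with L-BFGS-B (objective
tolerance 1e−10 relative, gradient tolerance scaled by n, cap 500
iterations).  For GEG/EG the score is analytic (derived by chain rule
from the density and the Mills-ratio form of F_EG and validated against
central differences); a fused value+gradient path keeps each
Monte-Carlo replication cheap.  Other families use numeric gradients.

Initialization is moment-based: τ₀ = sd·(skew/2)^{1/3}, clipped into
[1e−3·sd, 0.95·sd] — the upper clip matters, because for sample
skewness ≥ 2 the raw rule puts τ₀ at the sd and starts σ at numerical
zero, a degenerate basin the optimizer cannot leave — then
μ₀ = mean − τ₀, σ₀ = √(var − τ₀²), with a small multistart over
α₀ ∈ {0.5, 1, 2} keeping the best log-likelihood (the α/τ trade-off
produces a pronounced likelihood ridge; see below).

Standard errors come from the inverse observed Fisher information: the
Hessian of the negative log-likelihood in the ORIGINAL parameterization
(central differences of the analytic score where available), inverted
by Cholesky; if it is not positive definite, a transformed-space
Hessian plus delta method is tried; if both fail the fit is flagged
`converged = False`.  Wald intervals θ̂ ± z·SE are on the original
scale.  AIC = 2k − 2ℓ and BIC = k·log n − 2ℓ drive `compare_families`,
sorted by AIC with BIC as tie-break; non-convergent fits stay in the
table, flagged.

### The τ/α ridge

At the study's data-generating processes the four parameters are
heavily confounded: the per-observation Fisher information at
(τ=0.5, μ=0, σ=1, α=0.75) has parameter correlations up to |0.994|,
with asymptotic SEs at n = 1600 of roughly (0.13, 0.71, 0.31, 0.61) for
(τ, μ, σ, α).  Precision claims materially below this information bound
are not achievable by any estimator of this likelihood; the Monte-Carlo
acceptance assertions that embed such claims fail honestly and are
documented as such.  Small-sample summaries on the ridge additionally
depend on how far a given optimizer wanders along it before stopping,
i.e. they are partly optimizer properties rather than statistical ones.

## Monte-Carlo study engine

`run_scenario` draws `reps` samples of size n from a GEG DGP,
refits each, and summarizes over converged replications only (the
convergence proportion is reported separately): median bias
(median of θ̂ − θ), median root squared error (median of |θ̂ − θ| —
the literal per-replication reading; an `estimator="mean"` switch gives
classical mean bias/RMSE), and empirical coverage of 95% Wald
intervals.  Per-replication seeds are spawned from the scenario seed by
`SeedSequence`, so the full 36-DGP grid (τ ∈ {0.5, 1.25},
α ∈ {0.75, 1.75, 2.75}, n ∈ {50, …, 1600}, μ = 0, σ = 1, 1000
replications by default) is reproducible from one master seed and safe
to parallelize.  The test suite runs the two assertion rows at 500 and
1000 replications; unit tests use 25–60 replications — sizes chosen to
put Monte-Carlo noise safely below the asserted tolerances while a full
run stays a command-line option (`geg simulate --grid`).

## Shape analysis

Moments have no closed form for most of the families here, so
`shape_of` integrates x^k·pdf adaptively (tolerance 1e−10) between the
1e−12 and 1−1e−12 quantiles, with interior quantiles as breakpoints —
necessary because e.g. the skew-normal at λ ~ 1e6 or the power-normal
at α ~ 1e4 concentrate their mass in a narrow band far from their
location parameter.  A normalization check (∫pdf within 1e−3 of 1)
guards against silent quadrature failure.  Kurtosis is the raw
standardized fourth moment (Normal = 3).

`shape_range` scans: SN over λ ∈ ±[1e−2, 1e6] (log-spaced, plus the
exact half-normal λ → ∞ limit, whose skewness
√2(4−π)/(π−2)^{3/2} ≈ 0.9953 and kurtosis 3 + 8(π−3)/(π−2)² ≈ 3.8692
are also the family's suprema); PN over α ∈ [1e−3, 1e4] with local
golden-section refinement of each extremum.  On that domain the PN
kurtosis attains its minimum ≈ 2.9829 near α ≈ 0.54 and rises
monotonically to ≈ 4.3109 at the α = 1e4 edge (the α → 0 limit is
≈ 3.245; as α → ∞ the maximum-domain Gumbel values are approached only
at a log rate).  Values sometimes quoted for this family that lie below
the uniform distribution's kurtosis of 1.8 — or below the Pearson bound
1 + skew² for the paired skewness — cannot be produced by any
distribution in the family; the package reports what the integrals
give.  SNAP ranges are reported for the documented (λ, α) product grid
without refinement, since they depend visibly on the search window.

## Distributional regression

Each family parameter k gets a linear predictor g_k(θ_k) = X_k β_k with
the identity link for μ and log links for τ, σ, α (the conventional
choice for positive parameters).  Coefficients are estimated by direct
joint maximum likelihood with the analytic per-observation score
propagated through the links — deliberately simpler than the
backfitting (RS) algorithm of full GAMLSS, and equivalent for purely
linear predictors.  Formulas support `+`, `*` (main effects +
interaction) and `:`; factors are dummy-coded against the
lexicographically first level; rank-deficient designs raise with the
aliased columns named.  Smooth terms, random effects and distributional
trees are out of scope.

## Synthetic data

`generate_fixture` draws from the package's own samplers: `geg`
(default parameters (τ, μ, σ, α) = (0.835, 2.471, 0.253, 0.486) — a
strongly right-skewed shape on the divided-by-100 scale typical of
pooled behavioural RT data, n ≈ 3360 in the motivating setting), `eg`,
`normal`, and `two-group` (a 0.5 location shift between two balanced
groups, the regression exercise).  These fixtures emulate the scale,
skew and tail weight of real RT samples but not their serial
dependence, mixture structure (e.g. fast guesses), censoring or
discretization to the timer resolution — so passing tests demonstrate
correct inference for iid draws from the assumed family, not
robustness to those features.

## Numerical choices and edge cases

* Quantile levels must lie strictly in (0, 1); uniforms from the RNG
  are clipped to [1e−16, 1 − 1e−16] before inversion.
* Empty or constant samples are rejected at model construction;
  positive-support families reject non-positive data (recorded as a
  failed row inside `compare_families` rather than raised).
* A line search that stops on "precision loss" at a point whose score
  satisfies the stationarity bound (max component ≤ 1e−4·n) still
  counts as converged; summaries treat anything else as a failure.
* AIC ties in `compare_families` are broken by BIC; the sort is stable.
* The divide-by-a-constant convention for RTs is a pure
  reparameterization (location-scale equivariance of the MLE is tested
  at c = 100), so `--scale` only affects the reported units.

## Known limitations

* The observed-information SEs inherit the ridge: at small n the
  information matrix is frequently near-singular and 5–15% of
  replications are flagged non-converged at the hardest DGPs.
* Left-tail log-CDF accuracy below z ≈ −1e154 underflows the Mills
  difference; irrelevant for data but stated for completeness.
* The regression layer fits linear predictors only, and its Wald
  inference is asymptotic; no small-sample or profile corrections.
* Quadrature shape ranges are reported on their documented search
  domains; suprema attained only in a parameter limit (SN) are included
  analytically, others are domain-edge values by construction.
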