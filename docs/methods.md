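# Methods

## Model and estimation

The package estimates the spatial Durbin model (SDM)

    (I − ρW) y = α1 + Xβ + WXθ + ε,   ε ~ N(0, σ²I),

by maximum likelihood with the likelihood concentrated in ρ. For a
candidate ρ, regressing (I − ρW)y on Z = [1, X, WX] gives the closed-form
residual decomposition e(ρ) = e₀ − ρ e_d (e₀, e_d the residuals of y and
Wy on Z), hence σ²(ρ) = e(ρ)ᵀe(ρ)/n and the scalar profile

    ℓ(ρ) = −(n/2)(log 2πσ²(ρ) + 1) + log|I − ρW|.

The profile is maximized by bounded derivative-free (Brent-type) search
with tolerance 1e-8 in ρ over the open admissible interval
(1/λ_min, 1/λ_max) — (1/λ_min, 1) for row-standardized W — shrunk by an
absolute margin of 1e-5 at both ends. An optimum within 1e-6 of a bound, a
rank-deficient design, or a non-finite likelihood raises a structured
`ConvergenceError`; the package never returns a silently wrong fit.
Gaussian errors are assumed, as the likelihood requires; the data
generator offers Student-t errors for robustness experiments only.

The Jacobian term log|I − ρW| uses the precomputed spectrum of W when
n ≤ 4,000 and sparse LU factorization above that. For row-standardized W
built from a symmetric adjacency A, eigenvalues are taken from the similar
symmetric matrix D^(−1/2) A D^(−1/2), which guarantees a real spectrum;
island (zero-degree) areas contribute zero eigenvalues. The two log-det
paths agree to 1e-8 on the instances the tests cover.

The covariance of (α, β, θ, ρ) is the inverse negative Hessian of the full
log-likelihood, differentiated centrally with relative step 1e-5 in the
joint parameter (α, β, θ, ρ, σ²) and with σ² then marginalized out of the
reported block. A singular Hessian falls back to a pseudo-inverse with a
warning. `model_form="lag"` omits WX (the θ = 0 special case);
`model_form="ols"` is the aspatial baseline.

Missing values are refused rather than listwise-deleted, because deletion
would desynchronize rows from the weights matrix.

## Spatial weights

Weights are sparse throughout; dense conversions are confined to oracle
and eigenvalue paths and refused above n = 4,000. The underlying adjacency
must be symmetric: asymmetric input is symmetrized by union with a warning
(contiguity is symmetric by definition). Islands are retained as all-zero
rows, reported with a warning, excluded from Moran's S₀ by construction,
and contribute zero lag terms to estimation. The default lattice
contiguity is queen and the default transform row standardization — the
de-facto convention for US county analyses. GAL files follow the GeoDa
dialect (bare `n` header written; `0 n file var` headers also read);
edge-list CSVs (`id_from,id_to[,weight]`) are the second exchange format.
Polygon contiguity extraction and distance/kernel weights are out of
scope, as is weighting neighbor influence by population size.

## Effect decomposition and inference

Point estimates of the direct/indirect/total effects come from the
solve-based production path: with A = I − ρ̂W factorized once (sparse LU),
tr(A⁻¹) and tr(A⁻¹W) are accumulated from chunked solves against identity
and W columns, and the totals from one transposed solve of Aᵀv = 1. The
full n×n effect matrix, when requested, is likewise assembled from solves,
never an explicit inverse; the dense inverse appears only as the
brute-force oracle in tests.

Monte-Carlo inference samples (α, β, θ, ρ) from the asymptotic normal of
the ML estimates, rejecting draws with ρ outside the admissible interval
(a rejection rate above 10% is warned with its value). Per draw, the two
trace terms use the exact eigenvalue identities tr((I−ρW)⁻¹) = Σ 1/(1−ρλᵢ)
and tr((I−ρW)⁻¹W) = Σ λᵢ/(1−ρλᵢ) — a deliberate numerical choice: they are
exact for the symmetric-adjacency weights the package builds and make
thousands of draws cheap. Totals per draw use the closed form n/(1−ρ) for
island-free row-standardized W, and fall back to one sparse solve per draw
when islands are present. Two-sided p-values use the normal approximation
on the draw mean/SD (the conventional report); empirical-quantile p-values
are available by flag. Defaults: 1,000 draws, seed 0, both recorded in the
result object. The sampling-based scheme is the package's chosen
implementation of simulation inference for impact estimates; a full
Bayesian sampler is out of scope.

## Neighbor-order partitioning

The default grouping assigns to order q the q-th term of the geometric
expansion, ρ^q W^q (β_r I + θ_r W). This is the grouping under which the
zero-order indirect contribution equals θ_r — spillover exists even before
autoregressive feedback, matching how published decompositions of this
kind report a non-zero W₀ indirect column. The alternative grouping by
literal powers of W (which forces the W₀ indirect entry to zero) is
available via `grouping="by_power"`; both resum to the same totals.
Traces tr(W^q) come from the eigenvalue spectrum (sparse powers above the
dense threshold) and column sums 1ᵀW^q1 from iterated mat-vecs, so high
orders cost nothing; the default reporting order is Q = 4 with a
configurable ceiling, and the tail beyond Q is reported as a remainder
against the exact solve-based total.

## Synthetic data

The generator exists so every stage is testable with known ground truth.
Covariates are drawn as (I − ρ_x W)⁻¹ε and affinely rescaled to exact
target means/SDs; outcomes are drawn from the SDM process by sparse solve.
The demo preset targets the marginal means/SDs of a 2018 US county
mental-distress table (outcome mean 12.21, SD 1.88; a standardized
social-capital index with SD 1.26; ten further demographic covariates),
uses covariate spatial autocorrelation ρ_x = 0.6 (enough to produce the
strongly clustered quintile maps such data show), independent covariates
by default with an optional exact social-capital–SES correlation, and
Durbin parameters with the qualitative sign pattern of that literature
(negative own and spillover effects of social capital and SES). The demo
outcome is rescaled to its target marginal and clamped to (0, 100);
simulation-study mode never rescales or clamps, since either would bias
recovery experiments.

What the generator does not emulate: irregular county geometries and
degree heterogeneity of a real contiguity graph, covariate correlation
structure beyond the single configurable pair, non-Gaussian outcome noise
(except the optional t-errors), and measurement error in small-population
counties. Passing recovery tests on lattices therefore demonstrates
correctness of the estimator and decomposition arithmetic, not robustness
to those real-data features.

## Problem sizes and numerical choices

Recovery experiments use a 30×30 queen lattice (n = 900) with 50
replicates for bias summaries and 100 for Wald coverage — sizes at which
the sampling distribution of ρ̂ is tight (SE ≈ 0.04) while a full
experiment completes in seconds. Oracle-equivalence checks run at n = 225,
inside the dense threshold. Moran calibration uses 200 null replicates of
499 permutations on an 8×8 rook lattice; the permutation p-value uses the
standard +1 correction and is two-sided around E[I] = −1/(n−1). Quintile
boundaries use the type-7 empirical quantile convention (configurable);
ties always share a class. Composite indices use correlation-matrix PCA
(the inputs mix units), sign-anchored so a named input loads positively,
with scores standardized to mean 0 / SD 1. VIF regressions include an
intercept and report perfect collinearity as +inf rather than raising.

## Known limitations

- Impact Monte Carlo requires the spectrum of W, hence n ≤ 4,000 with the
  default threshold; point estimates and the fit itself scale further via
  sparse LU.
- The spatial-error and SARAR families, Bayesian estimation and
  heteroskedastic errors are not implemented.
- Asymmetric (e.g. k-nearest-neighbor) weights are not supported; the
  admissible-interval and eigenvalue machinery assumes a symmetric
  underlying adjacency.
- p-values for per-order partition terms inherit the normal approximation
  of the draw distribution; at high orders the terms are tiny and their
  significance flags should be read with corresponding caution.
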