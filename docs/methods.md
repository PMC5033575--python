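# Methods

This note records the statistical models implemented by `movewarp`, the
estimation procedures, the numerical choices that were genuinely open, and
what the synthetic-data generators do and do not emulate.

## 1. The hierarchical warping model

Observed signals are repeated functional observations
y_ij(t_k), i = 1..n_p participants, j = 1..n_r repetitions, on a common
domain [0, 1] (percentual or rescaled recorded time). The generative model
is

    y_ij(t) = (θ + φ_i) ∘ (ν_i + v_ij)(t) + x_ij(t) + ε_ij(t).

All random effects are scaled by the noise standard deviation σ, so the
likelihood depends on σ² only through a profile that can be maximized
analytically.

**Mean structure.** θ and φ_i live in a clamped cubic B-spline basis with
K equidistant knots on [0, 1] *including the boundaries*, giving K + 2
basis functions. (The alternative convention — K interior knots — changes
the meaning of cross-validated K values; the boundary-inclusive convention
is recorded here and in `SplineBasis`.) Participant deviations are kept
centered: after the per-participant ridge updates, the mean deviation is
moved into the template, leaving fitted values unchanged.

**Warps.** A warp is parametrized by its values at n_w equidistant
anchors in (0, 1); between anchors (and the pinned endpoints (0,0), (1,1))
it interpolates linearly. The participant warp ν_i carries free anchor
values; the repetition warp adds anchor deviations w_ij that interpolate
to 0 at both endpoints, with Brownian-bridge covariance
σ²γ²·min(t,t')(1−max(t,t')) — the bridge pins timing variation at
movement onset and offset, where the task constrains the movement.
Monotonicity is enforced by rejection (a barrier in the posterior, +inf in
`warp_posterior`, a gradient-carrying penalty inside the optimizer), not
by reparametrization, so the Gaussian prior on w stays interpretable; at
realistic variance scales the truncation is negligible and the simulator
redraws the rare invalid sample.

**Amplitude.** x_ij is a stationary Gaussian process with Matérn
covariance

    K(d) = σ²τ² · 2^{1−μ}/Γ(μ) · (αd)^μ K_μ(αd),

the *plain αd* convention: 1/α is the e-folding range at μ = 1/2 (where
the family is exponential). No √(2μ) factor is applied; μ values are not
transferable across conventions. S is indexed by *recorded* observation
times (|t_k − t_l| on the observed grid), attaching the process to
observations rather than to warped time. μ is a grid hyperparameter
(typically {0.5, 1, 2}), never optimized continuously: it changes the
meaning of (τ², α) and continuous optimization of smoothness is badly
conditioned.

### Estimation: three levels

1. **Fixed-warp level.** With warps fixed, GLS estimates
   ĉ = (Φ'(I+S)⁻¹Φ)⁻¹Φ'(I+S)⁻¹y over all curves (block-diagonal solves,
   one Cholesky per distinct time grid), then per participant the ridge
   estimate d̂_i with weight η = λ/(1+τ²). The normalization of η by the
   amplitude variance keeps one λ meaningful across conditions with
   different variance parameters; η is re-derived from λ after every
   variance update.
2. **Nonlinear level.** Per participant, (ν_i, {w_ij}) jointly minimize
   the negative log posterior (residual Mahalanobis norms under I+S plus
   the bridge prior on each w). The optimizer is bounded L-BFGS-B with
   analytic gradients assembled from the spline derivative and the
   hat-function warp Jacobian, started from the previous iterate and from
   the identity; if no valid descent below the identity warp exists, the
   identity is returned with a flag.
3. **Linearized level.** The model is linearized in w around the current
   predictions w⁰ (a Laplace approximation; the linearized mixed-model
   likelihood is exact for the linearized model). σ² is profiled
   analytically; (τ², α, γ²) are optimized on the log scale in
   [1e-10, 1e6] by L-BFGS-B from the current values plus two fixed
   neutral starts (the criterion can have distinct basins, e.g. amplitude
   variance collapsing toward zero; the lowest criterion value wins, and
   the result is never worse than the initialization). Per-curve V blocks
   are handled by one Cholesky per distinct grid plus a rank-n_w Woodbury
   update for the warp term; the full m×m matrix is never formed outside
   test oracles.

The outer/inner iteration alternates: inner loops re-predict warps and
re-estimate templates until the maximum absolute anchor change falls
below 1e-4; outer loops re-estimate variances at the new linearization
point. Five of each suffice in practice.

**Burn-in ridge.** The ridge on participant deviations exists to guide
alignment while the template is still poor: with a smeared initial
template and unpenalized deviations, participant timing differences are
absorbed as amplitude wiggles and the warps never move, which can end in
a misaligned state whose variance criterion is degenerate (σ̂²→0 with the
amplitude process absorbing the noise). `fit_pavpop` therefore uses
max(λ, 2.0) for the first two outer iterations and the configured λ
afterwards — alignment gets the stabilizing penalty, while the final
deviation and variance estimates are free of its shrinkage bias (a
permanently large λ inflates τ̂² several-fold by pushing participant-level
signal into the amplitude process). Both the burn-in weight and length
are `PavpopConfig` fields.

**Identifiability remarks.** A common shift of all ν_i against the
template is a near-flat direction of the joint criterion; it is harmless
for fitted values, classification and variance estimates (the reported
ν̂_i should be read relative to their own mean). The split between ν_i
and the w_ij means is identified by the mean-zero bridge prior: recovery
checks against known warps must use deviations with zero mean per anchor.

### Classification and cross-validation

`classify_tms` scores a test curve against every participant's fitted
template (θ̂+φ̂_i)∘ν̂_i by minimizing the posterior over the *test curve's*
w only — ν̂_i is a participant trait learned from training data — and
returns the argmin, ties to the lowest id. `chronological_cv_folds`
builds folds in repetition order (fold 1 tests repetitions 1..n/k, etc.),
respecting the temporal structure of repeated sessions.

## 2. The factor model for aligned paths

Aligned trajectories (30 time points × 3 coordinates, vectorized
time-major with coordinate fastest) are modelled as

    y_ijh = θ + (X_h β + Σ_{l=1..3} Z_{i,g_l(j,h),l}) W' + ε_ij,

θ fixed at the pointwise mean of the reference-height (lowest obstacle)
trajectories — it is a reference, not a parameter, and is not
re-estimated inside ECM. Height designs: ANOVA (S=(0,0), M=(1,0),
T=(0,1)) or linear height scaling (0 / 7.5 / 15 cm). The three latent
levels are participant (shared across a participant's curves), reaction
(participant×height) and repetition (per curve), each with a free q×q
covariance; ε has one variance per spatial coordinate (Λ floor 1e-12).
β is a pure fixed effect.

**ECM.** The E-step computes posterior moments of all latent units per
participant through the structured precision P = (D'D)⊗G + blockdiag of
prior precisions (D the unit-incidence matrix, G = W'Λ⁻¹W); participants
sharing a design pattern are batched through one factorization. The
observed log likelihood uses the matrix determinant lemma, so no 90·n_c
covariance is ever formed. CM steps run in Gauss–Seidel order
β → level covariances → Λ → W, the latter two using the fresh β so each
step conditionally maximizes Q; the unconstrained W update is followed by
QR re-orthonormalization with co-rotation of β and the level covariances
(a likelihood-preserving reparametrization). Indefinite intermediate
covariances are projected to the PSD cone with a warning.

**SQUAREM.** The squared-extrapolation scheme (S3 step length
α = −max(‖r‖/‖v‖, 1)) extrapolates the packed parameter vector (W; β;
Cholesky factors of the level covariances; log Λ), re-orthonormalizes W
after extrapolation, applies one stabilizing ECM step, and rejects any
extrapolation whose likelihood falls below the plain double ECM step —
the accepted-step trace is nondecreasing by construction. Convergence:
relative log-likelihood change below 1e-9, at most 500 ECM-equivalent
iterations. Initialization is deterministic (SVD of the centered data for
W, equal thirds of the score covariance for the levels), so fits are
bit-reproducible without any random seed.

**Identification.** W is orthonormalized; the rotation diagonalizing
Σ_l Σ_l is applied with the diagonal sorted decreasing; eigenvalue ties
break by the deterministic eigendecomposition order, and column signs
make each loading's largest-magnitude entry positive. The operation is
idempotent and likelihood-invariant.

**LRT of the height design.** The statistic 2(ll_ANOVA − ll_regression)
is referred to χ² with q degrees of freedom (one extra covariate column,
q slope parameters). Because ECM can settle in different basins for the
two designs, each design is also warm-started from the other's solution
(ANOVA can represent any regression solution exactly; the ANOVA effects
are projected onto the linear-scaling subspace for the reverse start) and
the better likelihood kept — this makes the nesting numerically robust. A
statistic below −1e-4·(1+|ll|) still raises a convergence error.
Calibration caveat: the χ² reference is asymptotic in the number of
participants; with very few participants (≲8) the test is anticonservative
because the extra ANOVA mean freedom partially exploits the estimated
rotation of W. The calibration study uses 12 participants × 3 repetitions,
where the empirical 5%-level rejection rate is nominal.

**Variance explained** per loading combines the covariate-driven variance
(empirical variance of (X_hβ)_k over the observed design) and the summed
level variances along that loading, relative to the total including
tr(Λ_full) = 30·Σ_d λ_d; the remainder is the noise share. **Prediction
ellipsoids** at a time point use the 3×q loading rows W_t:
cov = W_t Σ_level W_t', radii = sqrt(eigenvalues · χ²₃ quantile).

## 3. Preprocessing

* **Acceleration**: speed by central differences of positions at the T−2
  interior times; its derivative by finite differences over the interior
  grid (one-sided at the two ends), keeping length T−2. Only the speed
  magnitude enters, so the profile is invariant to rigid motions of the
  coordinate frame.
* **Percentual time**: onset/offset where |signal| crosses a configurable
  fraction (default 5%) of its peak — the exact threshold rule is a free
  choice; the default is recorded in `OnsetRule`.
* **Rescaling**: one affine map for the *whole dataset* (all conditions)
  to unit global value span and [0, 1] time span, with an invertible
  scale record. A per-condition rescaling would destroy cross-condition
  amplitude comparisons.
* **Path resampling**: each coordinate is smoothed by a least-squares
  cubic spline with 10 equidistant knots in *warped* percentual time and
  evaluated at 30 equidistant warped-time points, so the 30 samples are
  equidistant in aligned time and comparable across curves.

## 4. Synthetic data: what it does and does not emulate

`simulate_pavpop` draws from the exact generative model: template (default
a smooth double bump stored as spline weights, so the GLS update can
recover it without representation bias), Gaussian participant deviations
(centered), participant fixed-warp anchors (Gaussian around the identity,
sd 0.05, redrawn until valid — roughly ±5% timing traits, a realistic
magnitude for repeated reaching), Brownian-bridge random warps (rejection
on validity), exact multivariate-normal Matérn amplitude paths, and white
noise. Defaults are the study scale the model targets: 10 participants ×
10 repetitions, 50 points per curve, σ² = 1e-4 on unit-span data,
τ² = 1, α = 5, μ = 1, γ² = 0.25, n_w = 2, and participant amplitude
deviations with weight sd 0.1 (≈10% of the signal span).

`simulate_factor` draws the three nested levels with participant variation
largest and the height reaction smallest (per-loading sds 2.0/1.2/0.8,
0.4/0.3/0.2, 1.0/0.7/0.5 cm), a linear height effect of 0.15/0.05/0.02 cm
per cm of height increase along three smooth deterministic orthonormal
loadings, a canonical 40 cm transport path as θ, and 0.05 cm² noise per
coordinate.

What passing tests on these data *show*: the estimators recover the
quantities the models define, at realistic sizes and noise levels, from
data that satisfy the model assumptions exactly. What they do *not* show:
robustness to model violations present in real motion capture — marker
dropout beyond simple missingness, non-stationary amplitude noise,
non-Gaussian warp distributions, template shapes outside the spline span,
or sensor-specific artifacts.

## 5. Problem sizes and tolerances

Test and acceptance runs use desk-scale versions of each study: oracle
comparisons on 2-curve toys (tolerances 1e-10/1e-8 as pure linear-algebra
identities), Laplace-vs-quadrature on a 30-point single-anchor curve at
signal-to-noise 10 (2% relative), the recovery study at the full
10×10×50 scale with 20 replicates (median relative errors: a few percent
for σ², of the order of 10–20% for τ² and γ², depending on the seed),
classification with 3 participants ×
10 repetitions, factor subspace recovery at 10×10×3 with q = 3 (median
principal angle ≈ 9°), and the LRT null study at 12 participants × 3
repetitions × 3 heights with 200 replicates. Degenerate inputs are
handled explicitly: zero value span, flat signals (no onset), too-short
tracks, q above the data rank, coverage outside (0,1), invalid warps
(barrier, not error), and empty models all raise typed exceptions from
`movewarp.exceptions`.
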