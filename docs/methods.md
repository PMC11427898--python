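# Methods

## The problem

Bivariate allometry asks how a trait y (claw mass, ornament width,
brain mass) scales with a body-size measure x. The classical workflow —
log-transform both variables, fit a straight line by least squares,
exponentiate the line into the power law y = a·x^b — is valid only when
the data really are log-linear, and it silently commits the analyst to
a specific error model (multiplicative, lognormal, heteroscedastic).
`allomfit` implements the alternative protocol: fit a *pool* of
candidate mean functions to the untransformed observations by maximum
likelihood under an explicitly chosen error structure, rank the
candidates by AICc, check the residual assumptions, and report
profile-likelihood confidence intervals. The classical workflow is
recovered exactly as the special case POW2 + lognormal error, which the
test suite verifies to machine-level tolerance.

## Models and error structures

The pool (all logarithms natural):

| name    | mean function                     | mean params |
|---------|-----------------------------------|-------------|
| LINE0   | y = β₁x                           | 1 |
| LINE    | y = β₀ + β₁x                      | 2 |
| POW2    | y = a·x^b                         | 2 |
| POW3    | y = y₀ + a·x^b                    | 3 |
| SIG3    | y = A·x^h / (K^h + x^h)           | 3 |
| SIG4    | y = y₀ + A·x^h / (K^h + x^h)      | 4 |
| LOGLIN  | ln y = b₀ + b₁ ln x               | 2 |
| LOGQUAD | ln y = b₀ + b₁ ln x + b₂(ln x)²   | 3 |

The three-parameter sigmoid is the Hill form: it passes through the
origin, saturates at A, is S-shaped on arithmetic axes for h > 1, and
is nearly linear over a data range well below K. Published pool
comparisons of this kind rarely print their sigmoid equation; the Hill
form satisfies every property such analyses rely on (origin constraint,
late-onset curvilinearity) and is registered as a replaceable strategy
(`register_model`) so a logistic or Gompertz variant can be swapped in.

Error structures:

* **lognormal** (default): ε = ln(y_obs/y_pred) ~ N(0, σ²). The
  observation is lognormal around the predicted *geometric* mean, so the
  variance of y grows with its mean. This is exactly what a log-log OLS
  line assumes.
* **normal**: ε = y_obs − y_pred ~ N(0, σ²), additive and homoscedastic.

Likelihoods are densities of y on its original scale; the lognormal
density carries the per-observation Jacobian −ln y. Within one error
family that term is a data constant and cancels from every ΔAICc, but
keeping it makes cross-family comparisons meaningful rather than
silently wrong. Residuals are stored as ln(obs/pred) and reports state
the convention (some commercial packages flip the sign).

## Estimation

σ is concentrated out: for fixed mean parameters the ML estimate is
σ̂ = sqrt(mean ε²) (divisor n, not n−k, as AICc theory assumes), and the
profiled log-likelihood is a decreasing function of Σε². The mean
parameters are therefore estimated by trust-region least squares
(`scipy.optimize.least_squares`, TRF) on the residual vector, with
ftol = xtol = 1e-12, gtol = 1e-12, and a budget of 10,000 evaluations.

Numerical choices that matter:

* **Positivity.** Strictly positive parameters (a, A, K, h) are
  optimized on the log scale over (1e-20, 1e20). Besides enforcing the
  constraint, this flattens the K → ∞ ridge along which a sigmoid
  degenerates into a power law — in the original parameterization the
  optimizer crawls along that ridge; in log-K it converges in a few
  dozen evaluations and to a slightly better optimum.
* **Starts.** Power laws start from the log-log OLS line (POW3 also
  tries y₀ = min(y)/2); lines from OLS; sigmoids from a saturating
  start (A = 1.2·max y, K = median x, h = 2) and a near-linear start
  (K = 10·max x, h = 1). In `fit_pool`, a fitted simpler model seeds its
  nested extension (POW2 → POW3 with y₀ = 0, SIG3 → SIG4, LOGLIN →
  LOGQUAD, LINE0 → LINE). Up to five jittered restarts (seeded,
  default 20240916) run only if no start converges; fitting is
  deterministic.
* **Positivity of predictions.** Under lognormal error a trial θ whose
  mean dips below 1e-12 anywhere gets a smooth linear penalty pushing
  the prediction back positive; a converged fit whose final predictions
  are not all positive is flagged non-converged.
* **Degenerate fits.** Noise-free data drive σ̂ → 0 and the density
  degenerates; the fit reports σ̂ = 0, an infinite log-likelihood, and a
  warning, and profile intervals collapse onto the estimate.

k counts σ alongside the mean parameters (k = mean params + 1). The
printed convention of any one software package may differ; only AICc
*differences* matter for the ranking and the dominant contributions are
unaffected, but reports state the convention so users can reconcile.

## Selection

AICc = −2 logL + 2k + 2k(k+1)/(n−k−1); undefined (error) for
n ≤ k + 1. Models within 7 AICc of the best are flagged "worthy of
consideration" (the conventional 7–8 band; threshold configurable, and
the flag is read on ΔAICc, the literature convention, not on absolute
AICc). A richer model that fails to beat a nested simpler one by at
least 2 AICc earns an advisory overfitting note — the two fits carry
virtually the same information, so the extra parameter is not paying
its way. The note never eliminates automatically. Akaike weights are
reported as a convenience only. Ties in AICc are broken by smaller k,
then pool order. Non-converged fits stay in the table, flagged, and are
never "best".

## Profile-likelihood intervals

For a mean parameter θ_j the 95% bounds solve
2(logL_max − logL_profile(θ_j)) = χ²₁(0.95) = 3.841, with all other
parameters (and σ) re-optimized at each trial value. The search doubles
an initial step (1% of max(|θ̂_j|, 1)) away from the estimate until the
profile drops below the cutoff — at most 20 doublings, after which the
side is flagged open — then bisects the crossing to 1e-6 in
log-likelihood. Domain bounds (e.g. a > 0) clip the search; a side
pinned at a bound while still above the cutoff is likewise flagged.
For the exactly log-linear POW2 + lognormal case this interval is the
t-type interval with threshold sqrt((n−2)(e^{χ²/n} − 1)) ≈ 1.958 at
n = 51, i.e. analytic coverage 94.4% rather than 95% — the small-n cost
of the χ² calibration, which likelihood-ratio intervals accept by
construction.

## Diagnostics

Homoscedasticity: Breusch–Pagan score test of squared residuals against
the predictor, on the residual scale of the fit. Normality:
Shapiro–Wilk (3 ≤ n ≤ 5000). Both at α = 0.05, configurable; the tests
behind published qualitative "assumptions satisfied" statements are
seldom named, so standard, well-characterized tests are used and the
report names them. A normality failure affects probability statements,
not estimates, and the report text says so. R² is computed on the
fitting scale (log scale for lognormal error) about the mean of the
response on that scale; origin-constrained models can go negative
(reported, not clamped), and nonlinear arithmetic fits are labelled
pseudo-R². Lognormal-error predictions are geometric means; the two
smearing factors — parametric exp(σ̂²/2) and Duan's mean(exp ε̂) —
convert them to arithmetic means on request. The correction is
typically ~1–3% and does not change the perceived pattern.

## Biphasic fitting

The two-segment log-linear model profiles its breakpoint τ over the
deterministic grid of midpoints between consecutive sorted unique ln x
values leaving ≥ 3 points per segment; within segments OLS (continuity
at τ via a hinge design when requested). k = 4 mean parameters + τ + σ
(continuous: 3 + τ + σ). The default is two free lines. Because two
free segments nest the single log-line, the biphasic log-likelihood is
never below LOGLIN's — the AICc penalty is what protects the simpler
model. The package's artifact demonstration simulates from
y = 5 + 2·x^0.75 (a sublinear power law with a clearly non-zero
intercept, the shape reported for ontogenetic brain–body data) over
x ∈ [0.05, 10]: in the log domain the intercept bends the distribution
so LOGQUAD beats LOGLIN, while on the original scale POW3 beats the
biphasic fit — the "two growth phases" are a transformation artifact.

## Synthetic data

`generate(SimConfig)` draws x uniformly or log-uniformly over a stated
range and y from any pool model with either error structure; one
integer seed drives a single `numpy` Generator for both streams, so
datasets are bitwise reproducible. The generator emulates the
*statistical* shape of real morphometric samples — it does not emulate
measurement rounding, size-biased sampling, or high-leverage outliers,
so passing recovery tests demonstrate correctness of the estimation
machinery, not robustness to those real-data features.

Reference truths (one per model, used in recovery simulations) are
chosen to be biologically plausible over x ∈ [0.5, 20] with moderate
multiplicative noise σ = 0.1: e.g. POW2 (a = 0.3, b = 1.3), SIG3
(A = 10, K = 5, h = 2), LOGQUAD with slowly varying exponent
(b₂ = −0.15). Two fixtures mirror the protocol's motivating examples:

* `crab_like`: POW2 with b = 1.34, n = 51. The noise level (σ = 0.25)
  and body-mass range (uniform 0.3–3 g) are back-calculated from the
  published summaries of the real sample (log-scale R² ≈ 0.92, profile
  interval ≈ ±0.11 around the exponent); with that calibration the
  fixture also reproduces the sample's signature ambiguity — a straight
  line with negative intercept and the power law capture near-identical
  information, while the origin-constrained line is soundly rejected.
* `dobsonfly_like`: LINE (β₀ = 0.8, β₁ = 0.45 mm), σ = 0.06, n = 57,
  interantennal distance uniform on 5–12 mm — static allometry with a
  clearly positive intercept.

## Problem sizes

Simulation-based checks use 100–200 replicates per condition (500 for
the diagnostic calibration), n = 51–200 per dataset — enough for the
binomial error of an empirical rate to sit well inside the asserted
bands while the full suite runs in minutes on one core.

## Known limitations

* No measurement error in x (no RMA/major-axis estimators), no
  phylogenetic correction, no multivariate allometry — out of scope by
  design.
* Likelihood-ratio intervals only; no bootstrap or Bayesian intervals.
* The consideration threshold and the ΔAICc < 2 overfitting margin are
  conventions, not inferential guarantees; both are advisory flags.
* A 100-replicate coverage check of a 95% interval is itself binomial:
  even a perfectly calibrated interval lands outside 93–97/100 in
  roughly 3 of 10 blocks of seeds.
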