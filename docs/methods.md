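# Methods

## Model

`difml1` works with a MIMIC (multiple-indicators, multiple-causes) item
response model for two groups. The measurement part is a two-parameter
logistic model with a uniform (intercept-only) DIF effect,

    P(Y_ij = 1 | θ_i, x_i) = logistic(a_j θ_i + d_j + γ_j x_i),

together with local independence of the J items given (θ, x). The structural
part fixes the reference-group latent distribution to N(0, 1) — this pins the
scale and origin of the trait — and gives the focal group N(β, σ²). All
respondent-level traits are integrated out; the package never produces
per-respondent trait estimates. Parameters: a_j (discrimination, unitless
slope on the logit scale), d_j (easiness intercept), γ_j (DIF effect, a log
odds ratio), β (focal latent mean), σ² (focal latent variance).

## Identification: the minimal-L1 convention

For any c, replacing (β, γ_j) by (β + c, γ_j − a_j c) leaves the likelihood
unchanged, so the DIF effects are identified only up to this location shift
(for J ≥ 3 it is the only indeterminacy). Classical analyses resolve it by
declaring some items anchors (γ = 0 a priori). `difml1` instead selects the
representative whose DIF vector minimizes the convex piecewise-linear profile
h(c) = Σ_j |γ_j − a_j c|. This ML1 convention coincides with the sparsest
representative when DIF is sufficiently sparse, and it holds more generally
when positive and negative effects are roughly balanced.

Two checks are provided. `check_prop1` evaluates the exact sign condition:
with r_j = γ_j/a_j, c = 0 is the strict minimizer iff the left derivative of
h at 0 is negative and the right derivative positive, i.e.
Σ|a_j|(I(r_j < 0) − I(r_j ≥ 0)) < 0 and Σ|a_j|(I(r_j ≤ 0) − I(r_j > 0)) > 0.
`check_cor1` evaluates a simpler sufficient condition through the slope
spread ρ* = max|a|/min|a|: #{r_j ≤ 0} > ρ*·#{r_j > 0} and
#{r_j ≥ 0} > ρ*·#{r_j < 0}. The sufficient condition implies the exact one
(property-tested on 10⁴ random instances), never conversely.

## Estimation

**Stage 1 — constrained marginal MLE.** The marginal log-likelihood is
maximized over the P = 3J + 1 free parameters with γ₁ = 0 (any single item
may be pinned; the choice does not affect the final estimate, which is also
tested). The integral over θ uses fixed Gauss–Hermite quadrature after the
substitution θ = μ_g + √2 s_g t per group; the default is 31 nodes, and 21
nodes are indistinguishable at J = 25 (differences ≪ the optimizer
tolerance), so the replication engine and validation scripts use 21.
Logistic terms are evaluated with log1p/logaddexp forms so that extreme
logits (|a θ + d| > 30 occurs in quadrature tails) cannot overflow.

The optimizer is L-BFGS-B on the negative log-likelihood with analytic
gradients. The score reduces to matrix products involving the posterior node
weights (the per-respondent posterior over quadrature nodes), so one
function-plus-gradient evaluation is O(NK + NJ + JK) — a full J = 25,
N = 1000 fit takes well under a second. σ is optimized as log σ for
positivity; slopes are unconstrained but initialized at a_j = 1 (with
d_j = logit of the item proportion clipped to ±3, γ = 0, β = 0, σ = 1), a
neutral deterministic start that keeps the fit in the positive-slope mode.
Relative function tolerance 1e-10, max 500 iterations; restart-polish
experiments confirm the reported optima are converged to ≲1e-6.

**Covariance.** The scaled covariance of √N(Ξ̃ − Ξ†) is N·H⁻¹ with H the
observed information at Ξ̃, obtained by central finite differences of the
analytic score (step 1e-4·max(1, |param|), symmetrized). Differencing the
exact gradient is markedly better conditioned than double-differencing the
objective. Observed (not expected) information is used — it is available
without further integration and is the standard choice for Wald-type
uncertainty from a marginal likelihood. The result is symmetrized and its
eigenvalues floored at 1e-10·trace/P; a numerically singular H falls back to
a pseudo-inverse with a warning.

**Stage 2 — location correction.** Minimizing h(c) is a one-dimensional
least-absolute-deviations problem; its solution is the weighted median of
the breakpoints γ̃_j/ã_j with weights |ã_j|, computed exactly. When the
minimizing set is an interval (total weight splits exactly in half) the
lower endpoint is returned — deterministic and consistent with
quantile-regression conventions. Items with a_j = 0 contribute constants to
h and are excluded with a warning. The final estimate is
{β̃ + ĉ, σ̃², ã, d̃, γ̃ − ã ĉ}; the transform is idempotent, never increases
the L1 norm of the DIF vector, and preserves the likelihood exactly.

## Inference

Writing G_j(Ξ) for the j-th DIF effect of the ML1 representative of Ξ, the
error γ̂_j − γ*_j equals G_j(Ξ̃) − G_j(Ξ†) and its distribution is
approximated by M Monte-Carlo draws of G_j(Ξ̃ + Z/√N) − G_j(Ξ̃) with
Z ~ N(0, Σ̂_N) — a parametric bootstrap that needs only multivariate-normal
sampling and M weighted medians (vectorized; ~10⁴ draws in tens of
milliseconds). The pinned coordinate γ₁ receives no perturbation, but item 1
still varies through G₁'s dependence on every coordinate and is testable
like any other item.

From the draws D_j:

- **Confidence intervals** are basic (pivotal) bootstrap intervals
  [γ̂_j − q_{(1+L)/2}(D_j), γ̂_j − q_{(1−L)/2}(D_j)] at level L (default
  0.95).
- **p-values** are two-sided equal-tail add-one Monte-Carlo p-values,
  p_j = min(1, 2·min((1+#{D ≥ γ̂_j}), (1+#{D ≤ γ̂_j}))/(M+1)), with floor
  2/(M+1) and approximate null uniformity (KS distance < 0.1 against uniform
  in the validation study). An |D|-based symmetric variant would rank DIF
  items slightly more aggressively (≈ +0.02 AUC at N = 500 in our study);
  the equal-tail form is kept because it stays valid for skewed draw
  distributions.
- **Detection** applies the Benjamini–Hochberg step-up rule (via
  statsmodels) to the J p-values at FDR level α (default 0.05).

M defaults to 10,000 for simulation work and 50,000 for data analysis (the
CLI default). The exact interval/p-value constructions inside the bootstrap
were design choices; alternatives (percentile intervals, symmetric
p-values) shift third-decimal results.

## Anchor-based comparators

`lrt_anchor_test` implements the classical benchmark: with a known anchor
set A, fit the model with γ_j = 0 for j ∈ A, then refit per non-anchor item
with that item's effect also pinned (warm-started from the full fit);
2·(Δ log L) is floored at 0 and referred to χ²₁. With very few anchors the
per-item statistics are strongly positively correlated across items within
a dataset (they share the location information of the anchors), so
calibration assessments need many independent datasets, not many items.
`wald_anchor_intervals` provides observed-information Wald intervals under a
known anchor set for coverage comparisons. Default anchor choices in the
replication engine are the lowest-indexed items that are DIF-free in every
study design (1, 1–5, 1–10).

## Synthetic-data generator and validation study

The generator reproduces the validation design: J = 25 items, slopes cycling
(1.3, 1.4, 1.5, 1.7, 1.6), easiness either small (within ±1) or large
(within ±2), DIF vectors with 14/10/5 nonzero effects (high/medium/low) at
small (|γ| = 0.6–0.7) or doubled magnitude, mixed in sign so the ML1
condition holds in every design (asserted in tests); β = 0.5, σ = 0.5,
equal group sizes, N ∈ {500, 1000}. Respondent traits are drawn from the
group-specific normals and responses as independent Bernoullis from the item
response function. What it does *not* emulate about real data: missing
responses, non-normal or heteroscedastic-beyond-design trait distributions,
non-uniform DIF (group-varying slopes), local dependence, and more than two
groups — so passing tests certify the procedure under the model, not
robustness to these violations.

The replication engine derives per-replication seeds from a master seed via
SeedSequence counters (fully reproducible, parallel-safe), excludes and
counts failed fits (aborting a design past 10% failures), and aggregates:
item-averaged MSEs (σ reported as the SD, not the variance), empirical FDR
(per-replication false-discovery proportion, 0/0 → 0, averaged), per-item CI
coverage, and ROC/AUC. ROC curves rank items by p-value, are averaged
vertically (mean TPR on a fixed 512-point FPR grid, linear interpolation
within a replication), and AUC is the trapezoid area under the averaged
curve; for anchor-based methods only non-anchor items are scored.

Validation scale: the test suite and `scripts/acceptance.py` use 50
replications and M = 2000 (the published design used 100 and 10,000); at
this scale the Monte-Carlo standard error of an FDR estimate is ≈ 0.7
percentage points and of an AUC estimate ≈ 0.01, and simulation-based
assertions carry tolerances combining a relative band with 3× the
Monte-Carlo standard error computed from the replications themselves.

## Known limitations

- The ML1 convention fails when DIF is dense and one-directional (e.g. more
  than half the items shifted the same way under equal slopes); the
  condition checks can flag this only for hypothesized parameter values.
- Observed-information covariance plus the basic bootstrap gives slight
  finite-sample undercoverage (≈ 92–94% at nominal 95% with N ≤ 1000 in the
  validation designs).
- In our replications the focal-mean and focal-SD recovery errors
  (MSE ≈ 0.006 and 0.0015 at N = 1000) sit close to the delta-method
  prediction from the observed information, and the published counterparts
  are smaller; the DIF-effect and slope recovery — what the method is for —
  reproduces the published levels.
- Complete data only; respondents with missing responses are rejected, not
  imputed.
- Uniform DIF, two groups, binary items. Non-uniform DIF, multi-group,
  continuous covariates and ordinal models are out of scope.
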