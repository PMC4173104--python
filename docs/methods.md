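# Methods

This note documents the statistical models implemented in `centerbench`,
the numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Outcome model and direct standardization

All estimators build on the fixed-effects logistic outcome model

    E(Y | L, C=c) = expit(L'β + ψ_c),   c = 1..m,

with m center-indicator columns and **no global intercept** (each ψ_c
absorbs its center's intercept). Covariate effects β are constrained equal
across centers; covariates passed through the `interactions` hook receive a
separate coefficient per center instead. On a stratum-expanded registry
with all pattern columns interacted, the model is saturated and the fitted
probabilities equal the empirical stratum risks exactly — which is how the
model-based pipeline reproduces the closed-form `stratum_oracle` to 1e-8.

The directly standardized potential full-population risk is the plug-in

    Ê{Y(c)} = (1/n) Σ_i expit(L_i'β̂ + ψ̂_c),

averaging over **all** n patients, not only center c's own. Because the
logistic score equations force mean fitted = mean observed within each
center, a single-center registry returns exactly the observed event
proportion.

Indirect standardization reports, per center, the SMR — the model-based
risk of center c's own patients under c, divided by the unweighted mean
over all m centers c* of those same patients' risk under c* — and the
excess risk (difference instead of ratio). The denominator deliberately
weights centers equally, not by size.

### Firth correction

Small centers break plain ML: zero-event centers push ψ̂_c to −∞ and
quasi-separation inflates variance. The Firth-penalized likelihood

    l*(β, ψ) = l(β, ψ) + ½ log |I(β, ψ)|

(Jeffreys-prior penalization) is maximized by Newton iteration on the
modified score `Σ_i z_i [w_i(y_i − p_i) + h_i(½ − p_i)]`, where h_i is the
hat diagonal of the weighted design. For an intercept-only cell this has
the closed form `logit((events + ½)/(n + 1))`, which the tests use as an
oracle. Numerical policy: Newton steps with step-halving line search on
the penalized log-likelihood, tolerance 1e-8 on the score max-norm, cap
100 iterations; a gradient that plateaus below 1e-6 for 10 consecutive
iterations counts as converged (machine-precision stall). Plain-ML fits
whose gradient vanishes only because a parameter ran past ±15 on the logit
scale are flagged `converged=False` with the diverging columns named —
that is the separation signature, never silently truncated.

The delta-method variance of Ê{Y(c)} is `g' I⁻¹ g` with g the gradient of
the plug-in functional in (β, γ, ψ) and I the observed information at the
optimum (penalized fits reuse the unpenalized information, the standard
choice). Covariate variability is conditioned on, i.e. the L_i are treated
as the fixed standardization population.

### Bayesian mixed effects

The normal ME model adds ψ_c ~ N(μ_ψ, σ_ψ²) with hyperpriors
β_j ~ N(0, 10²), μ_ψ ~ N(0, 10²), σ_ψ ~ half-normal(1); the clustered
variant draws ψ_c from a K-component normal mixture with means
μ_k ~ N(0, 10²), sds σ_k ~ half-normal(1) and weights p ~ Dirichlet(1),
each center having equal prior probability of belonging to each cluster.
These hyperpriors are this package's defaults — weakly informative on the
logit scale and overridable per fit — since nothing stronger is available
in the provider-profiling literature for generic registries.

The posterior is sampled by an adaptive Metropolis-within-Gibbs scheme
written for this model family:

* ψ: per-center random-walk proposals, accepted independently and
  vectorized across centers (the ψ_c are conditionally independent given
  β); proposal scales adapt toward 0.44 acceptance during warmup with a
  (t+1)^{-0.6} Robbins-Monro schedule, initialized at 2.4/√(n_c+1);
* β: per-coordinate random-walk Metropolis;
* μ_ψ (and the μ_k): conjugate normal Gibbs draws;
* σ_ψ (and σ_k): random-walk Metropolis on log σ with the Jacobian term;
* clustered variant: cluster assignments z_c by exact Gibbs, weights by
  Dirichlet Gibbs; label switching is resolved by reordering clusters by
  ascending μ_k in every kept draw, and K=1 reduces exactly to the normal
  ME model.

Defaults are 4 chains × (1000 warmup + 1000 kept) draws; split-chain R-hat
and bulk ESS are computed via arviz and a threshold breach (default 1.01)
warns but still returns the draws with diagnostics attached. The
benchmark uses a leaner budget (2 × (400+400)) because it needs posterior
means and sds of a smooth m-dimensional functional, not tail quantiles.
Ê{Y(c)} and its sd are the across-draw mean and sd of the plug-in
functional, evaluated on up to 1000 evenly thinned draws.

### Doubly robust propensity-weighted estimation

The propensity score is the vector P(C=c | L), modeled either by
multinomial logistic regression (reference center's coefficients fixed at
0; own Newton solver, score equations satisfied to ≲1e-9) or, for large m
where multinomial fitting is fragile, by m one-vs-rest logistic fits whose
expit outputs are renormalized to sum to one per patient. One-vs-rest fits
that separate are refit with Firth correction and noted. Weights are
stabilized as `(n_c/n) / g(L_i, C_i)`; extreme weights are *reported*
(above a configurable percentile), never trimmed by default.

`dr_risk` refits the FE outcome model by weighted (optionally
Firth-corrected) regression and evaluates the same plug-in Ê{Y(c)}.
Because the weighted score equations hold, this plug-in provably equals
the augmented inverse-probability-weighted form

    (1/n) Σ_i [ f(L_i,c) + 1{C_i=c}/g(L_i,c) · (Y_i − f(L_i,c)) ],

which is what makes the estimator doubly robust: the correction term has
mean zero if the outcome model is right, and the rearranged form has mean
E{Y(c)} if the propensity model is right. The identity is asserted
internally to 1e-6 on every fit (a violation means broken score equations
and raises). Under Firth correction the weighted score is offset by the
known penalty term Σ h_i(½−p_i)z_i; the internal check adds this exactly
computable offset, so the assertion stays exact rather than loosened. The
reported estimate is always the weighted plug-in, which is guaranteed to
lie in [0,1].

Standard errors come from the sandwich over the stacked estimating
equations — propensity score, weighted outcome score, and the
standardization equation f(L_i,c) − μ_c — with the stabilization factors
n_c/n treated as known constants. The bread is a central-difference
Jacobian of the averaged estimating function (step 1e-6·(1+|θ|)), the meat
the empirical outer product. This is the standard M-estimation
reconstruction of the DR variance and reflects its characteristically
wider intervals; its finite-sample coverage is known to be below nominal
in small samples, matching the benchmark's observations.

## Classification

A center is flagged **low** iff `Ê{Y(c)} + z_k·sd < (1−λ)·E(Y)` and
**high** iff `(1+λ)·E(Y) < Ê{Y(c)} − z_k·sd`; everything else, including
exact threshold ties, is **accepted** (strict inequalities). E(Y) is the
sample mean of outcomes over the full registry (not leave-one-center-out;
a single shared benchmark keeps the criterion interpretable), or an
external reference value passed through unchanged. λ ≥ 0 is a clinical
tolerance (default 0.20), k ∈ (0.5, 1) the required evidence level
(default 0.75, z_k ≈ 0.674). With λ=0 and k=0.975 the rule is identical
to flagging when the 95% CI excludes E(Y). For an external benchmark the
package leaves λ fully user-specified. Ranking centers (by point estimate
or exceedance probability) is deliberately out of scope.

## Synthetic registries and the benchmark

`Scenario` defaults describe a register of 2355 patients in 63 centers
with a 22% marginal event rate — small-registry conditions where center
sizes are heavily skewed (log-normal, σ=1, floor 5, so very small centers
occur) and case-mix differs across centers. Covariates are independent
standard normals; center membership follows a softmax model whose
intercepts are the log size shares and whose slopes (sd 0.5 per covariate)
create confounding; outcomes are Bernoulli with logit
`L'β + ψ_C` (β = (0.7, 0.4) by default, moderate prognostic effects).
Optional centered-quadratic terms in the first covariate can enter the
outcome truth and/or the assignment truth; the registry then carries the
quadratic column so an analysis model can be deliberately correct or
misspecified.

True center effects (`psi_model="mixture"`) designate 30% of centers low
and 22% high. Class levels are solved by Gauss–Hermite quadrature so the
class-mean true potential risk sits at 0.70× / 1.00× / 1.35× the target
event rate, with within-class logit jitter (sd 0.05) small relative to the
tolerance band so designated classes coincide with realized classes.
Class designations are spread evenly across the size distribution
(balanced sequencing over size-ranked centers); with a skewed size law a
purely random assignment would let a handful of large centers drag the
marginal event rate off target. The truth-side benchmark for the three-way
class is the true marginal event rate E(Y) under the generative law
(estimated on a 200k-draw calibration sample), matching what the
estimation side benchmarks against (the sample mean); the realized rate
lands within Monte Carlo error of the 22% target.

`run_benchmark` draws replicates, fits the requested methods, classifies
with the scenario's (λ, k), and reports power, type-I error rates,
95%-interval coverage of the true potential risk, classified shares and
three-way accuracy, all in percent with replicate-level Monte Carlo
standard errors; failed fits are excluded from that method's denominator
and counted. Problem sizes in the shipped tests are chosen to make each
property decisive at desk scale: double-robustness bias checks use m=5
centers × 20 000 patients × 20 replicates; interval coverage uses m=10 ×
~500 patients/center × 500 replicates; the shrinkage power comparison uses
m=30 small centers (n≈450 total) × 200 replicates with the lean MCMC
budget.

What the generator does **not** emulate: correlated or categorical
covariates, outcome-dependent missingness (the complete-case filter is
exercised on independent missingness only), registry coverage bias
(selective non-registration of early deaths), time trends, and
center-by-covariate interaction truths. Passing benchmarks therefore
certify the estimators' statistical mechanics under clean confounding, not
robustness to those real-data pathologies.

## Degenerate inputs and tie-breaks

* Centers are opaque string labels, indexed in first-appearance order;
  all modules share that index and permuting labels permutes outputs.
* Stratum expansion requires integral expected event counts in
  `expected_counts` mode (tolerance 1e-9) and errors toward `integer`
  mode otherwise; emitted records are deterministically ordered.
* Complete-case filtering is idempotent, warns when a center loses all
  records or when >50% of records drop, and reports outcome-missing drops
  separately from covariate-missing drops (registries differ on how they
  handle missing outcomes; the package drops them but keeps the count
  visible).
* Rank-deficient designs raise with the aliased columns named rather than
  silently dropping them.
* `stabilize_weights` errors on a numerically zero propensity instead of
  producing an infinite weight.

## Known limitations

* The DR sandwich treats the stabilization factors as constants and
  ignores the Firth penalty's O(1) contribution to the outcome score; both
  are asymptotically negligible but contribute to the DR intervals'
  finite-sample under-coverage.
* The ME sampler is a random-walk scheme: effective sample sizes per
  iteration are modest compared to gradient-based samplers, so very large
  registries (say n ≫ 10⁵) would want longer chains.
* Only binary outcomes and weighting-based propensity adjustment are
  supported; time-to-event outcomes, matching and instrumental-variable
  approaches are out of scope.
* Frequentist BLUP-based mixed-effects fitting is intentionally absent;
  the Bayesian route gives posterior uncertainty for the standardization
  functional directly.
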