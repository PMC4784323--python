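# Methods

## Data-generating model

Outcomes are binary, nested as I individuals per household, J households per
village, K villages. The conditional (random-intercept) logistic model is

    logit π_ijk = α0 + x'_ijk α + u_k + z_jk,
    u_k ~ N(0, σ_v²),  z_jk ~ N(0, σ_h²),  independent,

with all probabilities evaluated through a numerically stable expit (the
linear predictor can reach |η| ≈ 10 at σ_v = log 5). Binary predictors are
*fixed by design*, not stochastic: each of five village profiles prescribes
the proportion of positive individuals, and designs with K > 5 replicate the
profiles in whole sets (so K must be a multiple of 5). Counts are realized
exactly — the number of positive households per village is round(J·p) for
household-level predictors (integral for every profile at J ∈ {20, 100}),
and round(J·I·p) positive individuals are drawn uniformly across the village,
ignoring household boundaries, for individual-level predictors. Exact counts
(rather than Bernoulli sampling per replicate) make each layout's predictor
ICC a fixed, known quantity: equal prevalence across villages of m = J·I
individuals gives exactly −1/(m−1), and a village-constant predictor gives
exactly 1. Which households or individuals receive the positive value is
randomized once per scenario and held fixed across replicates, so the
estimand is defined for the same design the estimator sees.

Defaults mirror the study conditions throughout: baseline log odds
α0 = log(0.1/0.9), conditional log OR α1 = log 2, household SD σ_h = log 2,
I = 5, J = 20, and σ_v swept over log(1.05)…log(5). The sweep is
discretized once as {log 1.05, log 1.5, log 2, log 3, log 5} — five points
spanning the range roughly evenly in outcome-ICC terms; results are smooth
in σ_v, so a finer grid changes the summaries only through Monte-Carlo noise.

## Estimation and intervals

The marginal model is fitted by Newton–Raphson on the score
U(β) = X'(y − π(β)) with step-halving on the deviance, convergence declared
at ‖U‖∞ ≤ 1e−10 within 50 iterations. The design matrix is checked for rank
by pivoted QR (collinear columns are named in the error). Separation is
flagged — never silently returned as converged — when any coefficient
exceeds 30 in absolute value or a fitted probability pins to 0/1 at machine
precision; at the study's sample sizes (N ≥ 500, ≥ 10% prevalence)
non-convergence is essentially absent, but high-ICC small-K cells can
separate in principle.

The cluster-robust covariance at clustering level g is B⁻¹MB⁻¹ with
B = X'V̂X and M = Σ_g s_g s_g' (s_g the cluster score sum), computed as an
outer product so it is positive semi-definite by construction. Cluster-
adjusted 95% intervals apply exactly two small-sample corrections — the
variance inflation n/(n−1) and a t(n−1) reference distribution, the
corrections available in standard survey software — and nothing else (no
CR2/CR3 bias reduction, no Satterthwaite-type degrees of freedom).
Unadjusted intervals use the model-based variance B⁻¹ with the normal
quantile 1.959964. Intervals are on the log-odds scale.

## The estimand

The true marginal coefficient vector solves the population score equations
Σ_u x_u(π̄_u − expit(x_u'β)) = 0, where π̄_u = E[expit(α0 + x_u'α + s)] with
s ~ N(0, σ_h² + σ_v²) — a 1-D Gaussian integral evaluated by Gauss–Hermite
quadrature. Forty nodes are the default; doubling to 80 changes the solution
by < 1e−8 across the parameter grid (guarded by a test), because the
integrand is smooth and the effective SD is at most √2·log 5 ≈ 2.3. The
root is found by Newton iteration (tolerance 1e−10 on the score sup-norm)
warm-started at the conditional parameters. The closed-form attenuation
β ≈ α(1 + c²(σ_h² + σ_v²))^{−1/2} with c = 16√3/(15π) is exposed as a
diagnostic; across the sweep it tracks the exact slope to within ~1.5% and
is never used as the coverage estimand.

## Intra-cluster correlations

The empirical predictor ICC is the pairwise moment estimator: the mean
cross-product of deviations over all within-cluster ordered pairs divided by
the overall variance, both with population (divide-by-N) moments. Only this
normalization reproduces the layouts' analytic values (−1/99, 0.19, 0.48, 1)
exactly; with unequal cluster sizes pairs are pooled (pair-weighted), which
leaves equal-size designs unaffected.

The model-based outcome ICC is defined conditionally on the covariates: the
covariance between two units induced by their shared random effects, with
each unit's covariate row held fixed, averaged over the design and divided
by the average Bernoulli variance μ(η)(1 − μ(η)). Village-level pairs are
taken from different households (sharing u only); household-level pairs
share both u and z. Expectations use nested Gauss–Hermite quadrature.
Conditioning on covariates makes the ICC zero at both levels when
σ_h = σ_v = 0 and identical across predictor layouts (all layouts have 20%
positives overall), so coverage curves for different layouts share one
x-axis. Evaluation at a single fixed linear predictor is also exposed.
The alternative, unconditional definition — which would add the clustering
carried by the covariate layout itself — is deliberately not the default.

## The coverage study

Each scenario computes the estimand once, then loops replicates:
simulate → fit → three interval types → containment indicator per slope.
Coverage is reported among converged fits (the primary convention), with a
secondary column counting non-converged replicates as non-covering; at the
study conditions the two coincide because every replicate converges.
Monte-Carlo SE is √(c(1−c)/n_converged). Seeds derive from
SeedSequence(root, scenario index, replicate index), making any cell
bit-reproducible in isolation.

Desk-scale runs use 2,000 replicates per cell (MC-SE ≈ 0.5 points at 95%
coverage); a full-fidelity run at 10,000 replicates is a flag away
(`--reps`) and scales linearly (~10 minutes for the full single-predictor
sweep). The joint model fits all seven predictors simultaneously with the
vector estimand from the same quadrature solver.

## Known limitations

- Balanced designs only (equal I and J everywhere), two levels, binary
  predictors and outcome; no weights, offsets or non-logit links.
- The simulated world matches the estimator's assumptions exactly (Gaussian
  random intercepts, fixed covariates, independent villages). Passing
  coverage here says nothing about misspecified random-effect distributions
  or informative cluster sizes in real data.
- Near the coverage boundary the minimum over sweep cells is a noisy,
  downward-selected statistic: at 2,000 replicates the weakest
  single-predictor cell (predictor ICC 0.48, σ_v = log 5) estimates ~83–84%
  against a bound of 85%, with MC-SE ≈ 0.8 points, so boundary checks are
  stated MC-SE-aware in the tests.
- Coverage of the village-constant layout with K = 5 is poor for every
  interval type; the study maps this region rather than fixing it.
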