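# crvecov

Coverage of cluster-robust confidence intervals in marginal logistic
regression when binary data are clustered at two nested levels — individuals
in households, households in villages.

## The problem

In epidemiological studies with nested clustering, point estimates from a
marginal (population-average) logistic model

    logit P(Y_ijk = 1 | x_ijk) = β0 + x'_ijk β

remain consistent when clustering is ignored, but the model-based standard
errors do not. The cluster-robust (sandwich) variance estimate

    B⁻¹ M B⁻¹,   B = Σ_j X_j' V_j X_j,   M = Σ_j X_j'(y_j − π̂_j)(y_j − π̂_j)' X_j

is consistent under arbitrary within-cluster dependence provided clusters
are independent — so adjusting at the *higher* level (village) is always
asymptotically valid ("passing the buck" upward). But there are fewer
villages than households, and with few clusters the sandwich estimate is
biased downward. This package quantifies that trade-off by simulation: data
are generated from a conditional (random-intercept) model

    logit π_ijk = α0 + x'_ijk α + u_k + z_jk,   u ~ N(0, σ_v²),  z ~ N(0, σ_h²),

the marginal model is fitted to each replicate, and 95% intervals are formed
three ways — unadjusted, household-adjusted, village-adjusted — with two
small-sample corrections on the adjusted ones (variance inflated by
n/(n−1) and a t(n−1) reference, n = number of clusters). Coverage is
measured against the *exact* marginal log odds ratio, computed by replacing
outcomes with their conditional-model expectations (a 1-D Gaussian integral
by Gauss–Hermite quadrature) and solving the marginal score equations.

The degree of clustering is organised by intra-cluster correlations (ICC):
the empirical pairwise ICC of each predictor layout and the model-implied
ICC of the outcome. Predictor layouts span the ICC range from the lower
bound −1/(m−1) (equal prevalence in every village) to 1 (village-constant).

## Worked example

```python
import numpy as np
from crvecov import (SimParams, build_design, simulate_outcomes, fit_marginal,
                     crve, corrected_ci, marginal_truth)

params = SimParams(alpha0=np.log(0.1/0.9), alpha=np.array([np.log(2)]),
                   sigma_h=np.log(2), sigma_v=np.log(2), I=5, J=20, K=5)
design = build_design(5, 20, 5, ("x1",), seed=1)
data = simulate_outcomes(design, params, seed=1)

fit = fit_marginal(data)
ci = corrected_ci(fit, crve(fit, design.village_id, "village"))[1]
truth = marginal_truth(design, params)
print(f"estimate {ci.estimate:.3f}, village-adjusted 95% CI ({ci.lower:.3f}, {ci.upper:.3f})")
print(f"true marginal log OR {truth.beta_true[1]:.3f} (conditional {np.log(2):.3f})")
```

prints

```
estimate 1.239, village-adjusted 95% CI (0.826, 1.651)
true marginal log OR 0.610 (conditional 0.693)
```

The conditional log odds ratio log 2 = 0.693 is attenuated to a marginal
0.610 by the two random effects (odds ratios are non-collapsible). Even
widened by the 5/4 variance inflation and the t(4) reference, this
replicate's village-adjusted interval happens to miss the truth — with only
K=5 villages such misses occur slightly more often than the nominal 5%,
which is exactly what the coverage study quantifies.

The numbered scripts under `analysis/` run the full study: predictor-layout
ICCs (`01`), exact vs closed-form marginal parameters (`02`), coverage
sweeps for single-predictor (`03`) and all-predictors (`04`) models, and the
coverage-vs-ICC figure (`05`). Each writes its table under `results/`.
A `crvecov` command-line tool exposes the same steps
(`simulate`, `fit`, `ci`, `icc`, `icc-model`, `true-beta`, `coverage`);
see `configs/` for a grid configuration example.

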