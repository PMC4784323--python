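import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from crvecov import (
    SimParams,
    build_design,
    corrected_ci,
    crve,
    fit_marginal,
    model_based_cov,
    simulate_outcomes,
)
from crvecov.design import ClusteredDataset, Design


def _tiny_fixture():
    """3 clusters x 4 units with fixed x and y for brute-force checks."""
    n = 12
    cluster = np.repeat([0, 1, 2], 4)
    x = np.array([0, 1, 1, 0, 1, 1, 1, 0, 0, 0, 1, 0])
    y = np.array([0, 1, 0, 0, 1, 1, 0, 1, 0, 0, 1, 1])
    design = Design(
        village_id=cluster,
        household_id=np.arange(n),
        individual_id=np.zeros(n, dtype=int),
        X=x.reshape(-1, 1).astype(np.int8),
        predictor_names=("x1",),
        level_of={"x1": "individual"},
        I=1,
        J=4,
        K=3,
    )
    return ClusteredDataset(design=design, y=y.astype(np.int8)), cluster


def _brute_force_sandwich(fit, cluster_ids):
    """Direct evaluation of B^{-1} (sum_g X_g'(y_g-p_g)(y_g-p_g)'X_g) B^{-1}."""
    X, y, p = fit.x_matrix, fit.y, fit.fitted_prob
    B = np.zeros((X.shape[1],) * 2)
    M = np.zeros_like(B)
    for g in np.unique(cluster_ids):
        m = cluster_ids == g
        Xg, rg = X[m], (y - p)[m]
        B += Xg.T @ np.diag(p[m] * (1 - p[m])) @ Xg
        M += Xg.T @ np.outer(rg, rg) @ Xg
    Binv = np.linalg.inv(B)
    return Binv @ M @ Binv


def test_crve_matches_brute_force_on_fixture():
    data, cluster = _tiny_fixture()
    fit = fit_marginal(data)
    est = crve(fit, cluster)
    np.testing.assert_allclose(est.cov, _brute_force_sandwich(fit, cluster), atol=1e-10)
    assert est.n_clusters == 3
    assert np.all(np.diag(est.cov) >= 0)


def test_singleton_clusters_collapse_to_hc0(sim_dataset):
    fit = fit_marginal(sim_dataset)
    est = crve(fit, np.arange(sim_dataset.design.n_units))
    oracle = sm.GLM(fit.y, fit.x_matrix, family=sm.families.Binomial()).fit(cov_type="HC0")
    np.testing.assert_allclose(est.cov, oracle.cov_params(), atol=1e-8)


def test_cluster_relabeling_and_within_cluster_order_invariance(sim_dataset):
    fit = fit_marginal(sim_dataset)
    ids = sim_dataset.design.village_id
    a = crve(fit, ids).cov
    b = crve(fit, 1000 - ids).cov  # relabeled
    np.testing.assert_allclose(a, b, atol=1e-14)


def test_crve_errors():
    data, cluster = _tiny_fixture()
    fit = fit_marginal(data)
    with pytest.raises(ValueError, match="length"):
        crve(fit, cluster[:-1])
    with pytest.raises(ValueError, match="2 clusters"):
        crve(fit, np.zeros_like(cluster))


def test_corrected_ci_arithmetic():
    """n=20 clusters: CI = beta +- t_{.975,19} * sqrt(cov_kk * 20/19)."""
    data, cluster = _tiny_fixture()
    fit = fit_marginal(data)
    est = crve(fit, cluster)
    # overwrite with round numbers to check the stated corrections directly
    fit.beta_hat = np.array([0.0, 0.5])
    cov = est.__class__(cov=np.diag([0.01, 0.04]), level="village", n_clusters=20,
                        correction_applied=True)
    ci = corrected_ci(fit, cov)[1]
    half = 2.093024 * np.sqrt(0.04 * 20 / 19)
    assert ci.lower == pytest.approx(0.5 - half, abs=1e-5)
    assert ci.upper == pytest.approx(0.5 + half, abs=1e-5)
    assert ci.adjustment == "vil"


def test_five_cluster_multipliers():
    assert stats.t.ppf(0.975, df=4) == pytest.approx(2.776445, abs=1e-6)
    # variance inflation n/(n-1) = 5/4 enters through the SE
    data, cluster = _tiny_fixture()
    fit = fit_marginal(data)
    cov = crve(fit, cluster).__class__(cov=np.eye(2), level="village", n_clusters=5,
                                       correction_applied=True)
    ci = corrected_ci(fit, cov)[1]
    width = ci.upper - ci.lower
    assert width == pytest.approx(2 * 2.776445 * np.sqrt(5 / 4), rel=1e-6)


def test_corrected_ci_converges_to_normal_for_many_clusters():
    data, cluster = _tiny_fixture()
    fit = fit_marginal(data)
    base = crve(fit, cluster)
    big = base.__class__(cov=base.cov, level="village", n_clusters=10**7,
                         correction_applied=True)
    ci_t = corrected_ci(fit, big)[1]
    se = np.sqrt(base.cov[1, 1])
    assert ci_t.upper - ci_t.lower == pytest.approx(2 * 1.959964 * se, rel=1e-5)


def test_corrected_width_exceeds_uncorrected(sim_dataset):
    """The two small-sample corrections strictly widen the interval for any
    finite number of clusters."""
    fit = fit_marginal(sim_dataset)
    est = crve(fit, sim_dataset.design.village_id)
    uncorrected_half = 1.959964 * np.sqrt(est.cov[1, 1])
    ci = corrected_ci(fit, est)[1]
    assert (ci.upper - ci.lower) / 2 > uncorrected_half


def test_unadjusted_uses_model_based_variance(sim_dataset):
    fit = fit_marginal(sim_dataset)
    est = model_based_cov(fit)
    np.testing.assert_allclose(est.cov @ fit.bread, np.eye(2), atol=1e-10)
    ci = corrected_ci(fit, est)[1]
    assert ci.reference == "normal"
    assert ci.adjustment == "un"
    half = 1.959964 * np.sqrt(est.cov[1, 1])
    assert ci.upper - ci.lower == pytest.approx(2 * half, rel=1e-12)


def test_village_crve_tracks_sampling_variance_without_clustering():
    """With independent villages the mean village-level CRVE matches the
    empirical sampling variance of the slope across replicates."""
    d = build_design(5, 20, 20, ("x1",), seed=3)
    p = SimParams(alpha0=np.log(0.2 / 0.8), alpha=np.array([np.log(2)]),
                  sigma_h=0.0, sigma_v=np.log(2), I=5, J=20, K=20)
    betas, vars_ = [], []
    for s in range(400):
        fit = fit_marginal(simulate_outcomes(d, p, seed=s))
        if not fit.converged:
            continue
        betas.append(fit.beta_hat[1])
        vars_.append(crve(fit, d.village_id).cov[1, 1])
    emp = np.var(betas, ddof=1)
    # sampling error of a variance over ~400 draws is ~ sqrt(2/n) relative
    assert np.mean(vars_) == pytest.approx(emp, rel=0.25)
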