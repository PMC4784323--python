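import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crvecov import SimParams, build_design, empirical_icc, outcome_icc_model, simulate_outcomes

LOG2 = float(np.log(2.0))
A0 = float(np.log(0.1 / 0.9))

# analytic pairwise ICCs for the four household-level layouts at villages of
# 100 individuals, via (m*B - s^2)/((m-1)*s^2) with population moments
EXPECTED_ICC = {"x1": -1 / 99, "x2": 3.04 / 15.84, "x3": 7.54 / 15.84, "x4": 1.0}


@pytest.mark.parametrize("name,expected", sorted(EXPECTED_ICC.items()))
def test_village_level_predictor_iccs(name, expected):
    d = build_design(5, 20, 5, (name,), seed=13)
    est = empirical_icc(d.column(name), d.village_id, name)
    assert est.value == pytest.approx(expected, abs=1e-12)


def test_equal_prevalence_attains_lower_bound():
    """Identical prevalence in every cluster of size m gives exactly -1/(m-1)."""
    d = build_design(5, 20, 5, ("x1",), seed=2)
    est = empirical_icc(d.column("x1"), d.village_id)
    assert est.value == pytest.approx(-1 / 99, abs=1e-12)


def test_cluster_constant_variable_gives_one():
    values = np.repeat([3.0, 7.0, 1.0], 10)
    ids = np.repeat([0, 1, 2], 10)
    assert empirical_icc(values, ids).value == pytest.approx(1.0, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(a=st.floats(0.1, 10), b=st.floats(-5, 5), data=st.data())
def test_empirical_icc_affine_and_relabel_invariance(a, b, data):
    rng = np.random.default_rng(data.draw(st.integers(0, 2**20)))
    values = rng.integers(0, 2, size=60).astype(float)
    ids = np.repeat(np.arange(6), 10)
    if values.min() == values.max():
        return
    base = empirical_icc(values, ids).value
    assert empirical_icc(a * values + b, ids).value == pytest.approx(base, rel=1e-9, abs=1e-12)
    assert empirical_icc(values, 17 - ids).value == pytest.approx(base, abs=1e-12)
    assert -1 / 9 - 1e-12 <= base <= 1 + 1e-12


def test_empirical_icc_errors():
    with pytest.raises(ValueError, match="constant"):
        empirical_icc(np.ones(10), np.repeat([0, 1], 5))
    with pytest.raises(ValueError, match="2 clusters"):
        empirical_icc(np.arange(10.0), np.zeros(10))


def _params(sigma_h=LOG2, sigma_v=LOG2):
    return SimParams(alpha0=A0, alpha=np.array([LOG2]), sigma_h=sigma_h, sigma_v=sigma_v,
                     I=5, J=20, K=5)


def test_outcome_icc_zero_without_random_effects(x1_design):
    p = _params(sigma_h=0.0, sigma_v=0.0)
    assert outcome_icc_model(p, x1_design, "village").value == pytest.approx(0.0, abs=1e-12)
    assert outcome_icc_model(p, x1_design, "household").value == pytest.approx(0.0, abs=1e-12)


def test_village_icc_zero_without_village_effect(x1_design):
    """sigma_v=0 with a village-balanced covariate leaves no between-village
    variation in the mean outcome."""
    p = _params(sigma_v=0.0)
    assert outcome_icc_model(p, x1_design, "village").value == pytest.approx(0.0, abs=1e-10)
    assert outcome_icc_model(p, x1_design, "household").value > 0


def test_village_icc_monotone_in_sigma_v(x1_design):
    values = [
        outcome_icc_model(_params(sigma_v=float(sv)), x1_design, "village").value
        for sv in np.log([1.05, 1.5, 2, 3, 5])
    ]
    assert all(a < b for a, b in zip(values, values[1:]))


def test_outcome_icc_matches_monte_carlo(x1_design):
    """Pair-product Monte-Carlo oracle for the model-based outcome ICC.

    Units have fixed covariates, so the per-unit replicate mean estimates
    mu(eta) and the ICC is the covariate-conditional within-cluster pair
    covariance over the mean Bernoulli variance.
    """
    p = _params()
    model_v = outcome_icc_model(p, x1_design, "village").value
    model_h = outcome_icc_model(p, x1_design, "household").value

    d = x1_design
    rng = np.random.default_rng(6)
    R = 3000
    ys = np.stack([simulate_outcomes(d, p, rng).y for _ in range(R)]).astype(float)
    mu_hat = ys.mean(axis=0)  # empirical marginal probability per unit
    denom = np.mean(mu_hat * (1 - mu_hat))

    num_v = n_v = 0.0
    num_h = n_h = 0.0
    for k in range(d.K):
        idx = np.where(d.village_id == k)[0]
        h = d.household_id[idx]
        P = ys[:, idx].T @ ys[:, idx] / R  # E[y_r y_s]
        C = P - np.outer(mu_hat[idx], mu_hat[idx])
        same_hh = h[:, None] == h[None, :]
        diag = np.eye(len(idx), dtype=bool)
        num_v += C[~same_hh].sum()
        n_v += (~same_hh).sum()
        num_h += C[same_hh & ~diag].sum()
        n_h += (same_hh & ~diag).sum()
    rho_v_mc = (num_v / n_v) / denom
    rho_h_mc = (num_h / n_h) / denom

    assert model_v == pytest.approx(rho_v_mc, abs=0.01)
    assert model_h == pytest.approx(rho_h_mc, abs=0.01)


def test_outcome_icc_errors(x1_design):
    with pytest.raises(ValueError, match="level"):
        outcome_icc_model(_params(), x1_design, "region")
    degenerate = SimParams(alpha0=80.0, alpha=np.array([0.0]), sigma_h=0.0, sigma_v=0.0,
                           I=5, J=20, K=5)
    with pytest.raises(ValueError, match="degenerate"):
        outcome_icc_model(degenerate, x1_design, "village")
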