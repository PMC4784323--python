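"""Intra-cluster correlations (ICC) for predictors and outcomes.

Two estimators live here.  ``empirical_icc`` is the moment estimator of the
pairwise ICC: the mean cross-product of deviations over all within-cluster
ordered pairs, divided by the overall (population-moment) variance.  For
equal cluster size m it reduces to (m*B - s^2) / ((m-1)*s^2), where B is the
population variance of cluster means and s^2 the overall population
variance, and is bounded below by -1/(m-1).  Population (divide-by-N)
moments are used throughout — the convention under which a predictor with
identical prevalence in every cluster of size 100 gives exactly -1/99.

``outcome_icc_model`` computes the model-implied ICC of the binary outcome
under the conditional logistic model, by nested Gauss-Hermite quadrature
over the village and household random effects, averaging over the design's
covariate rows (population-averaged) or at a single fixed linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import Design, SimParams
from .truth import DEFAULT_GH_NODES, _gh_rule, marginal_prob

from scipy.special import expit

__all__ = ["ICCEstimate", "empirical_icc", "outcome_icc_model"]


@dataclass(frozen=True)
class ICCEstimate:
    value: float
    variable: str
    level: str  # "household" or "village"
    kind: str  # "empirical" or "model_based"
    m: float  # cluster size (mean size if unequal)


def empirical_icc(
    values: np.ndarray,
    cluster_ids: np.ndarray,
    variable: str = "",
    level: str = "village",
) -> ICCEstimate:
    """Pairwise moment estimator of the ICC of ``values`` within ``cluster_ids``.

    Pairs are pooled across clusters, so unequal cluster sizes are pair-
    weighted; a cluster-constant variable gives exactly 1.

    Raises
    ------
    ValueError
        If the input is constant, has fewer than 2 clusters, or no cluster
        contains 2 or more units.
    """
    z = np.asarray(values, dtype=float)
    labels, inverse = np.unique(np.asarray(cluster_ids), return_inverse=True)
    if labels.shape[0] < 2:
        raise ValueError("at least 2 clusters are required")
    mu = z.mean()
    s2 = np.mean((z - mu) ** 2)
    if s2 == 0.0:
        raise ValueError("values are constant; ICC is undefined")
    d = z - mu
    sum_d = np.zeros(labels.shape[0])
    sum_d2 = np.zeros(labels.shape[0])
    sizes = np.bincount(inverse).astype(float)
    np.add.at(sum_d, inverse, d)
    np.add.at(sum_d2, inverse, d**2)
    if (sizes >= 2).sum() == 0:
        raise ValueError("no cluster contains 2 or more units")
    # sum over ordered within-cluster pairs (i != i*) of d_i d_{i*}
    pair_sum = np.sum(sum_d**2 - sum_d2)
    n_pairs = np.sum(sizes * (sizes - 1))
    rho = (pair_sum / n_pairs) / s2
    return ICCEstimate(value=float(rho), variable=variable, level=level, kind="empirical", m=float(sizes.mean()))


def outcome_icc_model(
    params: SimParams,
    design: Design,
    level: str = "village",
    eta: float | None = None,
    n_nodes: int = DEFAULT_GH_NODES,
) -> ICCEstimate:
    """Model-based ICC of the outcome at the household or village level.

    The ICC is computed at given covariate values — the covariance induced by
    the shared random effects between two units with fixed linear predictors,
    not the clustering carried by the covariate layout itself — and averaged
    over the design: the mean within-cluster pair covariance divided by the
    mean Bernoulli variance mu(eta)(1-mu(eta)).  Village-level pairs share
    the village effect only (different households); household-level pairs
    share both effects.  Expectations use nested Gauss-Hermite quadrature.
    With ``eta`` given, the covariate part of the linear predictor is held at
    that single value instead of averaging over the design rows.
    """
    if level not in ("household", "village"):
        raise ValueError(f"level must be 'household' or 'village', got {level!r}")
    if eta is None:
        eta_rows = params.alpha0 + design.X @ params.alpha
    else:
        eta_rows = np.full(design.n_units, float(eta))

    u_nodes, u_w = _gh_rule(params.sigma_v**2, n_nodes)
    z_nodes, z_w = _gh_rule(params.sigma_h**2, n_nodes)

    mu_rows = np.asarray(marginal_prob(eta_rows, params.sigma_total_sq, n_nodes))
    mu = float(mu_rows.mean())
    if mu <= np.finfo(float).eps or mu >= 1.0 - np.finfo(float).eps:
        raise ValueError("marginal prevalence is degenerate (0 or 1)")
    denom = float(np.mean(mu_rows * (1.0 - mu_rows)))

    num = 0.0
    cnt = 0.0
    if level == "village":
        # pairs from the same village but different households share only u;
        # a_r(u) = E_z expit(eta_r + u + z)
        for k in range(design.K):
            mask = design.village_id == k
            rows = eta_rows[mask]
            hh = design.household_id[mask]
            grid = rows[:, None, None] + u_nodes[None, :, None] + z_nodes[None, None, :]
            a = expit(grid) @ z_w  # (units, u)
            _, inv = np.unique(hh, return_inverse=True)
            hh_sums = np.zeros((inv.max() + 1, a.shape[1]))
            np.add.at(hh_sums, inv, a)
            pair_u = a.sum(axis=0) ** 2 - (hh_sums**2).sum(axis=0)  # per u node
            mus = mu_rows[mask]
            mu_hh = np.zeros(inv.max() + 1)
            np.add.at(mu_hh, inv, mus)
            mu_pairs = mus.sum() ** 2 - (mu_hh**2).sum()
            m = rows.shape[0]
            sizes = np.bincount(inv)
            num += float(pair_u @ u_w) - mu_pairs
            cnt += m**2 - (sizes**2).sum()
    else:
        # pairs from the same household share both u and z
        n_households = design.household_id.max() + 1
        cache: dict[tuple, float] = {}
        for h in range(n_households):
            rows = np.sort(eta_rows[design.household_id == h])
            key = tuple(rows.tolist())
            if key not in cache:
                grid = rows[:, None, None] + u_nodes[None, :, None] + z_nodes[None, None, :]
                a = expit(grid)  # (units, u, z)
                pair_uz = a.sum(axis=0) ** 2 - (a**2).sum(axis=0)
                mus = np.asarray(marginal_prob(rows, params.sigma_total_sq, n_nodes))
                mu_pairs = mus.sum() ** 2 - (mus**2).sum()
                cache[key] = float(u_w @ pair_uz @ z_w) - float(mu_pairs)
            num += cache[key]
            m = (design.household_id == h).sum()
            cnt += m**2 - m
    rho = (num / cnt) / denom
    m_size = design.J * design.I if level == "village" else design.I
    return ICCEstimate(value=float(rho), variable="y", level=level, kind="model_based", m=float(m_size))
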