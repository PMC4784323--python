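"""Cluster-robust (sandwich) variance estimation and corrected confidence intervals.

The sandwich estimator at a clustering level g is

    B^{-1} M B^{-1},   B = X'VX,   M = sum_g s_g s_g',
    s_g = X_g'(y_g - pi_hat_g),

consistent under arbitrary within-cluster dependence provided clusters are
independent.  Two small-sample corrections are applied to cluster-adjusted
intervals: the variance is inflated by n/(n-1) (n = number of clusters) and
the reference distribution is t with n-1 degrees of freedom.  Unadjusted
intervals use the model-based variance B^{-1} with a standard-normal
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fit import MarginalFit

__all__ = [
    "CovarianceEstimate",
    "ConfidenceInterval",
    "crve",
    "model_based_cov",
    "corrected_ci",
]

Z_975 = 1.959964  # standard-normal 97.5% quantile, as conventionally rounded


@dataclass(frozen=True)
class CovarianceEstimate:
    """A (p+1)x(p+1) coefficient covariance with its clustering level.

    ``level`` is "none" for the model-based (inverse bread) variance,
    otherwise the clustering level the sandwich was computed at.
    ``correction_applied`` records whether interval construction will apply
    the n/(n-1) and t_{n-1} corrections.
    """

    cov: np.ndarray
    level: str
    n_clusters: int
    correction_applied: bool


@dataclass(frozen=True)
class ConfidenceInterval:
    name: str
    estimate: float
    lower: float
    upper: float
    level_nominal: float
    adjustment: str  # "un", "hh" or "vil"
    reference: str  # "normal" or "t(df)"

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def model_based_cov(fit: MarginalFit) -> CovarianceEstimate:
    """Model-based variance (inverse observed information), no clustering."""
    cov = np.linalg.inv(fit.bread)
    return CovarianceEstimate(cov=cov, level="none", n_clusters=len(fit.y), correction_applied=False)


def crve(fit: MarginalFit, cluster_ids: np.ndarray, level: str = "cluster") -> CovarianceEstimate:
    """Cluster-robust sandwich covariance B^{-1} (sum_g s_g s_g') B^{-1}.

    ``cluster_ids`` are per-unit labels partitioning the observations; with
    every unit its own cluster this reduces to the HC0 heteroskedasticity-
    robust estimator.
    """
    cluster_ids = np.asarray(cluster_ids)
    if cluster_ids.shape[0] != fit.y.shape[0]:
        raise ValueError("cluster_ids length does not match the fitted data")
    labels, inverse = np.unique(cluster_ids, return_inverse=True)
    n_clusters = labels.shape[0]
    if n_clusters < 2:
        raise ValueError("at least 2 clusters are required for a cluster-robust variance")
    resid = fit.y - fit.fitted_prob
    scores = np.zeros((n_clusters, fit.x_matrix.shape[1]))
    np.add.at(scores, inverse, fit.x_matrix * resid[:, None])
    # B^{-1} (S'S) B^{-1} computed as (B^{-1}S')(B^{-1}S')' so the result is
    # positive semi-definite by construction
    half = np.linalg.solve(fit.bread, scores.T)
    cov = half @ half.T
    cov = (cov + cov.T) / 2.0
    return CovarianceEstimate(cov=cov, level=level, n_clusters=n_clusters, correction_applied=True)


def corrected_ci(
    fit: MarginalFit,
    cov: CovarianceEstimate,
    alpha_level: float = 0.05,
    adjustment: str | None = None,
) -> list[ConfidenceInterval]:
    """Confidence intervals for all coefficients from a covariance estimate.

    Cluster-adjusted intervals (level != "none") use
    SE = sqrt(n/(n-1) * cov_kk) and the t_{1-alpha/2, n-1} quantile;
    unadjusted intervals use the raw SE with the normal quantile.
    """
    if adjustment is None:
        adjustment = {"none": "un", "household": "hh", "village": "vil"}.get(cov.level, cov.level)
    var = np.diag(cov.cov).copy()
    if cov.level == "none":
        mult = Z_975 if alpha_level == 0.05 else stats.norm.ppf(1 - alpha_level / 2)
        reference = "normal"
    else:
        n = cov.n_clusters
        if n < 2:
            raise ValueError("adjusted intervals require at least 2 clusters")
        var *= n / (n - 1.0)
        mult = stats.t.ppf(1 - alpha_level / 2, df=n - 1)
        reference = f"t({n - 1})"
    se = np.sqrt(var)
    out = []
    for k, name in enumerate(fit.coef_names):
        est = float(fit.beta_hat[k])
        half = float(mult * se[k])
        out.append(
            ConfidenceInterval(
                name=name,
                estimate=est,
                lower=est - half,
                upper=est + half,
                level_nominal=1 - alpha_level,
                adjustment=adjustment,
                reference=reference,
            )
        )
    return out
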