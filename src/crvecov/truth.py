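"""True marginal parameters implied by the conditional (random effects) model.

A conditional logistic model with Gaussian random intercepts implies a
marginal (population-average) model whose log odds ratios are attenuated
toward the null.  The exact marginal coefficients are obtained by solving
the marginal-model score equations with outcomes replaced by their
conditional-model expectations,

    sum_u x_u (pibar_u - expit(x_u' beta)) = 0,
    pibar_u = E[ expit(alpha0 + x_u'alpha + s) ],  s ~ N(0, sigma_h^2 + sigma_v^2),

the expectation computed by Gauss-Hermite quadrature over the fixed
simulation design.  The closed-form approximation of Zeger, Liang & Albert,

    beta ~= alpha (1 + c^2 (sigma_h^2 + sigma_v^2))^{-1/2},  c = 16 sqrt(3)/(15 pi),

is provided as a diagnostic; it is never the coverage estimand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .design import Design, SimParams

__all__ = ["ZEGER_C", "MarginalTruth", "marginal_prob", "marginal_truth", "true_beta", "zeger_beta"]

ZEGER_C = 16.0 * np.sqrt(3.0) / (15.0 * np.pi)

DEFAULT_GH_NODES = 40


def _gh_rule(sigma_sq: float, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for E[f(s)], s ~ N(0, sigma_sq), via Gauss-Hermite."""
    t, w = np.polynomial.hermite.hermgauss(n_nodes)
    return np.sqrt(2.0 * sigma_sq) * t, w / np.sqrt(np.pi)


def marginal_prob(
    eta: float | np.ndarray, sigma_total_sq: float, n_nodes: int = DEFAULT_GH_NODES
) -> float | np.ndarray:
    """Marginal success probability E[expit(eta + s)], s ~ N(0, sigma_total_sq)."""
    if sigma_total_sq < 0:
        raise ValueError("sigma_total_sq must be non-negative")
    eta_arr = np.asarray(eta, dtype=float)
    if sigma_total_sq == 0.0:
        out = expit(eta_arr)
    else:
        nodes, weights = _gh_rule(sigma_total_sq, n_nodes)
        out = expit(eta_arr[..., None] + nodes) @ weights
    return float(out) if np.isscalar(eta) or eta_arr.ndim == 0 else out


@dataclass(frozen=True)
class MarginalTruth:
    """Exact and approximate marginal coefficients for one conditional model."""

    beta_true: np.ndarray  # (intercept, slopes), from quadrature + root-finding
    beta_zeger: np.ndarray  # slopes only, Eq.-style closed form
    sigma_total_sq: float
    c_const: float = ZEGER_C

    def slope(self, index: int) -> float:
        return float(self.beta_true[index + 1])


def zeger_beta(params: SimParams) -> np.ndarray:
    """Closed-form attenuation of the conditional slopes."""
    factor = (1.0 + ZEGER_C**2 * params.sigma_total_sq) ** -0.5
    return params.alpha * factor


def true_beta(
    design: Design,
    params: SimParams,
    predictors: list[str] | tuple[str, ...] | None = None,
    n_nodes: int = DEFAULT_GH_NODES,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """Exact marginal coefficients (intercept first) for the given design.

    Solves the population score equations by Newton iteration on the smooth
    deterministic score; the "population" is the fixed design itself, so the
    estimand matches what the marginal fit estimates under that design.

    Raises
    ------
    RuntimeError
        If the Newton iteration fails to converge (the message reports the
        residual norm).
    """
    if predictors is None:
        predictors = list(design.predictor_names)
    cols = [np.ones(design.n_units)]
    for name in predictors:
        cols.append(design.column(name).astype(float))
    X = np.column_stack(cols)
    alpha_full = np.array(
        [params.alpha[design.predictor_names.index(p)] for p in predictors]
    )
    eta_cond = params.alpha0 + X[:, 1:] @ alpha_full
    pibar = np.asarray(marginal_prob(eta_cond, params.sigma_total_sq, n_nodes))

    beta = np.concatenate(([params.alpha0], alpha_full))  # warm start
    for _ in range(max_iter):
        p = expit(X @ beta)
        score = X.T @ (pibar - p)
        if np.max(np.abs(score)) <= tol:
            return beta
        w = p * (1.0 - p)
        info = (X * w[:, None]).T @ X
        beta = beta + np.linalg.solve(info, score)
    resid = np.max(np.abs(X.T @ (pibar - expit(X @ beta))))
    raise RuntimeError(f"true-beta solver did not converge; score residual {resid:.3e}")


def marginal_truth(
    design: Design,
    params: SimParams,
    predictors: list[str] | tuple[str, ...] | None = None,
    n_nodes: int = DEFAULT_GH_NODES,
) -> MarginalTruth:
    """Bundle the exact and closed-form marginal parameters."""
    return MarginalTruth(
        beta_true=true_beta(design, params, predictors, n_nodes=n_nodes),
        beta_zeger=zeger_beta(params),
        sigma_total_sq=params.sigma_total_sq,
    )
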