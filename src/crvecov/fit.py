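"""Maximum-likelihood fit of the marginal (population-average) logistic model.

The marginal model logit P(Y=1|x) = x'beta is fitted by Newton-Raphson on
the score U(beta) = X'(y - pi(beta)), with step-halving on the deviance.
Clustering is ignored at the fitting stage; it enters only through the
variance estimate (see :mod:`crvecov.sandwich`).  The fit exposes the
"bread" matrix X'VX (V = diag(pi(1-pi))) that the sandwich estimator needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr
from scipy.special import expit

from .design import ClusteredDataset

__all__ = ["MarginalFit", "fit_marginal", "SCORE_TOL", "MAX_ITER", "SEPARATION_BOUND"]

SCORE_TOL = 1e-10
MAX_ITER = 50
# |beta| beyond this on the log-odds scale is treated as (quasi-)separation
SEPARATION_BOUND = 30.0


@dataclass
class MarginalFit:
    """Result of a marginal logistic fit.

    ``beta_hat`` is ordered (intercept, then predictors); ``bread`` is the
    observed information X'VX at the estimate.  ``converged`` is False when
    the iteration cap was reached or separation was detected; the best
    iterate is still reported.
    """

    beta_hat: np.ndarray
    fitted_prob: np.ndarray
    bread: np.ndarray
    converged: bool
    n_iter: int
    coef_names: tuple[str, ...]
    x_matrix: np.ndarray
    y: np.ndarray

    @property
    def score(self) -> np.ndarray:
        return self.x_matrix.T @ (self.y - self.fitted_prob)


def _check_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # -2 log-likelihood, computed stably via logaddexp
    return 2.0 * float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def fit_marginal(
    dataset: ClusteredDataset,
    predictors: list[str] | tuple[str, ...] | None = None,
    tol: float = SCORE_TOL,
    max_iter: int = MAX_ITER,
) -> MarginalFit:
    """Fit logit P(Y=1|x) = beta0 + x'beta by maximum likelihood.

    Parameters
    ----------
    dataset
        Simulated or loaded clustered data; clustering is ignored here.
    predictors
        Predictor columns to include (default: all columns in the design).

    Raises
    ------
    ValueError
        If the design matrix (with intercept) is rank deficient (the error
        names the collinear columns) or the outcome is constant.
    """
    design = dataset.design
    if predictors is None:
        predictors = list(design.predictor_names)
    y = dataset.y.astype(float)
    if y.min() == y.max():
        raise ValueError("outcome is constant; the intercept is not identifiable")

    cols = [np.ones(design.n_units)]
    for name in predictors:
        cols.append(design.column(name).astype(float))
    X = np.column_stack(cols)
    names = ("intercept", *predictors)
    _check_rank(X, names)

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    dev = _deviance(y, eta)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = expit(eta)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) <= tol:
            converged = True
            break
        w = p * (1.0 - p)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving: accept the first step that does not increase deviance
        lam = 1.0
        for _ in range(30):
            eta_new = X @ (beta + lam * step)
            dev_new = _deviance(y, eta_new)
            if dev_new <= dev + 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        eta = X @ beta
        dev = _deviance(y, eta)

    p = expit(eta)
    if np.max(np.abs(X.T @ (y - p))) <= tol:
        converged = True
    # separation: runaway coefficients or probabilities pinned to 0/1
    eps = np.finfo(float).eps
    if np.max(np.abs(beta)) > SEPARATION_BOUND or p.min() <= eps or p.max() >= 1.0 - eps:
        converged = False

    w = p * (1.0 - p)
    bread = (X * w[:, None]).T @ X
    return MarginalFit(
        beta_hat=beta,
        fitted_prob=p,
        bread=bread,
        converged=converged,
        n_iter=n_iter,
        coef_names=names,
        x_matrix=X,
        y=y,
    )
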