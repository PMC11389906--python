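"""Small dense Newton solvers for binary logistic regression.

These are deliberately minimal: the fits inside recursive feature
elimination run tens of thousands of times on matrices with a few dozen
rows, where the overhead of a general-purpose solver dominates.  The
ridge penalty (never applied to the intercept) keeps the Hessian
invertible in tiny, separable folds.
"""

from __future__ import annotations

import numpy as np

__all__ = ["logistic_fit", "sigmoid", "LogisticFitResult"]

_CLIP = 30.0


def sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_CLIP, _CLIP)))


class LogisticFitResult:
    __slots__ = ("beta", "converged", "n_iter", "loglik", "separated", "cov")

    def __init__(self, beta, converged, n_iter, loglik, separated, cov=None):
        self.beta = beta
        self.converged = converged
        self.n_iter = n_iter
        self.loglik = loglik
        self.separated = separated
        self.cov = cov


def _loglik(X, y, beta):
    eta = np.clip(X @ beta, -_CLIP, _CLIP)
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-8,
    compute_cov: bool = False,
) -> LogisticFitResult:
    """Maximum-likelihood logistic fit by Newton with step halving.

    ``X`` must already contain an intercept column in position 0; the
    ridge penalty ``ridge/2 * ||beta[1:]||^2`` is subtracted from the
    log-likelihood and never touches the intercept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    pen_mask = np.ones(p)
    pen_mask[0] = 0.0

    def objective(b):
        return _loglik(X, y, b) - 0.5 * ridge * float((pen_mask * b * b).sum())

    obj = objective(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = sigmoid(X @ beta)
        w = pi * (1.0 - pi)
        grad = X.T @ (y - pi) - ridge * pen_mask * beta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        H = (X.T * w) @ X + ridge * np.diag(pen_mask)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving keeps the (penalized) log-likelihood monotone
        new_beta = beta + step
        new_obj = objective(new_beta)
        halvings = 0
        while new_obj < obj and halvings < 25:
            step *= 0.5
            new_beta = beta + step
            new_obj = objective(new_beta)
            halvings += 1
        beta, obj = new_beta, new_obj
    separated = (not converged) or bool(np.max(np.abs(beta)) > 15.0)
    cov = None
    if compute_cov:
        pi = sigmoid(X @ beta)
        w = pi * (1.0 - pi)
        H = (X.T * w) @ X + ridge * np.diag(pen_mask)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
    return LogisticFitResult(beta, converged, it, _loglik(X, y, beta), separated, cov)
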