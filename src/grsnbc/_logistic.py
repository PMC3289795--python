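"""Small Newton/IRLS fitter for binomial logistic models on grouped data."""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class FittingError(RuntimeError):
    """Logistic fit failed to converge."""


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Maximum-likelihood fit of a binomial logistic model.

    Parameters
    ----------
    X : (n, p) design matrix.
    y : (n,) outcomes; either 0/1 labels or success proportions for
        grouped observations.
    weights : (n,) observation weights (group totals for grouped data).

    Returns
    -------
    (coefficients, standard errors, iterations used).

    Raises
    ------
    FittingError
        If the gradient norm does not fall below ``tol`` within
        ``max_iter`` Newton steps.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    beta = np.zeros(X.shape[1])
    for iteration in range(1, max_iter + 1):
        p = expit(X @ beta)
        grad = X.T @ (w * (y - p))
        if np.max(np.abs(grad)) < tol:
            info = X.T @ (X * (w * p * (1.0 - p))[:, None])
            se = np.sqrt(np.diag(np.linalg.inv(info)))
            return beta, se, iteration
        info = X.T @ (X * (w * p * (1.0 - p))[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise FittingError(f"singular information matrix at iteration {iteration}") from exc
        # damp very large steps so near-separated fits fail loudly, not with overflow
        biggest = np.max(np.abs(step))
        if biggest > 10.0:
            step *= 10.0 / biggest
        beta = beta + step
    raise FittingError(f"no convergence after {max_iter} iterations")
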