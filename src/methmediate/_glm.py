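"""Minimal Newton-Raphson logistic regression.

Written for the specific workload of this package: many maximum-likelihood
fits of tiny models (n of order 100, at most a handful of columns) inside
the causal-inference component tests. Step-halving Newton with a
separation guard keeps the log-likelihood monotone and flags
(quasi-)separated fits.
"""

from __future__ import annotations

import numpy as np

_ETA_CAP = 30.0  # |linear predictor| beyond this signals (quasi-)separation


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-12,
) -> tuple[np.ndarray, float, bool]:
    """Maximum-likelihood logistic fit of y on design X (with intercept column).

    Returns ``(beta, loglik, converged)``.  ``converged`` is False under
    complete/quasi-complete separation (diverging linear predictor) or if
    Newton fails to converge within ``max_iter``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    ll = _loglik(eta, y)
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, ll, False
        # step-halving to guarantee monotone log-likelihood
        for _ in range(30):
            beta_new = beta + step
            eta_new = X @ beta_new
            ll_new = _loglik(eta_new, y)
            if ll_new >= ll - 1e-14:
                break
            step *= 0.5
        delta = ll_new - ll
        beta, eta, ll = beta_new, eta_new, ll_new
        if np.max(np.abs(eta)) > _ETA_CAP:
            return beta, ll, False
        if abs(delta) < tol:
            return beta, ll, True
    return beta, ll, False
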