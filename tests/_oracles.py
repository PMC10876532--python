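"""Independent reference implementations used only to check the package."""

from __future__ import annotations

import numpy as np


def irls_poisson(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> np.ndarray:
    """Hand-rolled iteratively reweighted least squares for the Poisson GLM.

    Solves the normal equations (X' W X) d = X' (y - mu) with W = diag(mu)
    until the coefficient update is below ``tol``.  Kept deliberately
    independent of any GLM library.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8)) - np.log(np.exp(offset).mean())
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = np.exp(eta)
        step = np.linalg.solve(X.T @ (X * mu[:, None]), X.T @ (y - mu))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta
    raise RuntimeError("IRLS oracle did not converge")


def dl_pool(y, se):
    """Direct DerSimonian-Laird formulas (moment estimator)."""
    y = np.asarray(y, dtype=float)
    se = np.asarray(se, dtype=float)
    w = 1.0 / se**2
    ybar = np.sum(w * y) / np.sum(w)
    Q = np.sum(w * (y - ybar) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (len(y) - 1)) / denom)
    ws = 1.0 / (se**2 + tau2)
    pooled = np.sum(ws * y) / np.sum(ws)
    return pooled, tau2, np.sqrt(1.0 / np.sum(ws))


def hungarian_cosine_match(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Best one-to-one matching of columns of A to columns of B by cosine.

    Returns the matched cosine similarities (length = n columns of A).
    """
    from scipy.optimize import linear_sum_assignment

    An = A / np.linalg.norm(A, axis=0, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    C = An.T @ Bn
    r, c = linear_sum_assignment(-C)
    return C[r, c]
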