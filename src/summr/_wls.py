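"""Weighted least squares with a multiplicative random-effects floor.

All MR regression estimators here are weighted linear regressions of
outcome betas on exposure betas with weights 1/se_y^2.  Under the
multiplicative random-effects model the coefficient standard errors are
scaled by sqrt(Q/df) but never below the fixed-effect value (sigma >= 1),
the convention of summary-data MR software.
"""

from __future__ import annotations

import numpy as np

from .datatypes import InputError


def weighted_least_squares(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                           effects_model: str = "multiplicative_random"):
    """Fit y ~ X with weights w; no implicit intercept.

    Returns ``(params, se, q, df, sigma)`` where ``q`` is the weighted
    residual sum of squares, ``df = k - p`` and ``sigma`` the SE scaling
    actually applied (1 under the fixed-effect model).
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1 and len(y) > 1:
        X = X.T
    y = np.asarray(y, float).ravel()
    w = np.asarray(w, float).ravel()
    k, p = X.shape
    if k <= p:
        raise InputError(f"need more SNPs ({k}) than parameters ({p})")

    Xw = X * w[:, None]
    A = X.T @ Xw
    if np.linalg.matrix_rank(A) < p:
        raise InputError(_collinearity_message(X))
    params = np.linalg.solve(A, Xw.T @ y)
    cov_unscaled = np.linalg.inv(A)
    resid = y - X @ params
    q = float(np.sum(w * resid ** 2))
    df = k - p
    if effects_model == "multiplicative_random":
        sigma = max(1.0, np.sqrt(q / df))
    elif effects_model == "fixed":
        sigma = 1.0
    else:
        raise InputError(f"unknown effects_model {effects_model!r}")
    se = np.sqrt(np.diag(cov_unscaled)) * sigma
    return params, se, q, df, sigma


def _collinearity_message(X: np.ndarray) -> str:
    p = X.shape[1]
    corr = np.corrcoef(X, rowvar=False) if p > 1 else np.ones((1, 1))
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)
             if abs(corr[i, j]) > 0.999]
    if pairs:
        return ("exposure beta matrix is rank deficient; near-collinear "
                f"column pairs (0-based): {pairs}")
    return "exposure beta matrix is rank deficient"
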