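"""Independent brute-force oracles shared across test modules."""

import numpy as np
from scipy.special import expit


def irls_logistic(X, y, tol=1e-12, max_iter=200):
    """Newton-Raphson (IRLS) maximum-likelihood logistic fit; returns
    [intercept, coefficients...].  Independent of every code path it checks."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X1.shape[1])
    for _ in range(max_iter):
        p = expit(X1 @ beta)
        W = p * (1 - p)
        grad = X1.T @ (y - p)
        hess = (X1 * W[:, None]).T @ X1
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta
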