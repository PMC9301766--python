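"""Cyclic coordinate descent for weighted-L1 penalized least squares.

Minimizes (1/2n)||y - X b||^2 + lambda * sum_j w_j |b_j| on precomputed Gram
matrices.  Per-coefficient penalty factors w_j allow covariates to enter
unpenalized (w_j = 0) alongside penalized item predictors (w_j = 1).  Zeros
produced by the soft threshold are exact.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def cd_gram(XtX, Xty, w, lam, n, beta, tol, max_iter):
    """In-place cyclic coordinate descent on the Gram system.

    A predictor with XtX[j, j] <= 0 (zero variance) is pinned at zero.
    Convergence: max absolute coefficient change in a sweep < tol.
    Returns the number of sweeps performed.
    """
    m = beta.shape[0]
    sweeps = 0
    for _ in range(max_iter):
        sweeps += 1
        max_delta = 0.0
        for j in range(m):
            d = XtX[j, j]
            if d <= 0.0:
                beta[j] = 0.0
                continue
            # gradient of the smooth part with b_j removed:
            # g = x_j' (y - X b_{-j})
            g = Xty[j] + d * beta[j]
            for u in range(m):
                g -= XtX[j, u] * beta[u]
            z = g / n
            t = lam * w[j]
            if z > t:
                nb = (z - t) * n / d
            elif z < -t:
                nb = (z + t) * n / d
            else:
                nb = 0.0
            delta = abs(nb - beta[j])
            if delta > max_delta:
                max_delta = delta
            beta[j] = nb
        if max_delta < tol:
            break
    return sweeps


@njit(cache=True)
def cd_gram_path(XtX, Xty, w, lams, n, tol, max_iter):
    """Warm-started solution path over a descending lambda grid."""
    m = XtX.shape[0]
    L = lams.shape[0]
    betas = np.zeros((L, m))
    beta = np.zeros(m)
    for l in range(L):
        cd_gram(XtX, Xty, w, lams[l], n, beta, tol, max_iter)
        betas[l] = beta
    return betas
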