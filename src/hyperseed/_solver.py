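"""Numba kernels for the penalized logistic coordinate-descent solver.

All kernels operate on column-standardized design matrices and minimize the
per-sample objective

    f(b0, b) = (1/n) sum_i [ log(1 + exp(eta_i)) - y_i eta_i ] + lam * ||b||_1

via iteratively reweighted least squares (outer loop) with cyclic
soft-threshold coordinate updates (inner loop).  The intercept is never
penalized.  Convergence is declared when a full outer iteration moves no
coefficient by more than ``tol``.
"""

import numpy as np
from numba import njit

_MAX_OUTER = 250
_WEIGHT_FLOOR = 1e-6


@njit(cache=True)
def _soft(x, t):
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True)
def fit_one_standardized(Z, y, lam, beta0_init, beta_init, tol, max_sweeps):
    """Fit a single lambda from a warm start.

    Returns (beta0, beta, total_coordinate_sweeps, converged).
    """
    n, p = Z.shape
    beta = beta_init.copy()
    beta0 = beta0_init
    total_sweeps = 0
    converged = False
    for outer in range(_MAX_OUTER):
        # quadratic (IRLS) approximation at the current coefficients
        eta = np.zeros(n)
        for j in range(p):
            bj = beta[j]
            if bj != 0.0:
                for i in range(n):
                    eta[i] += Z[i, j] * bj
        w = np.empty(n)
        r = np.empty(n)
        wsum = 0.0
        for i in range(n):
            e = eta[i] + beta0
            if e > 0.0:
                pr = 1.0 / (1.0 + np.exp(-e))
            else:
                ex = np.exp(e)
                pr = ex / (1.0 + ex)
            # saturate fitted probabilities (glmnet convention): keeps the
            # IRLS curvature bounded away from zero on separable data
            if pr > 1.0 - 1e-5:
                pr = 1.0 - 1e-5
            elif pr < 1e-5:
                pr = 1e-5
            wi = pr * (1.0 - pr)
            if wi < _WEIGHT_FLOOR:
                wi = _WEIGHT_FLOOR
            w[i] = wi
            r[i] = (y[i] - pr) / wi  # working residual at the expansion point
            wsum += wi
        wz2 = np.empty(p)
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * Z[i, j] * Z[i, j]
            wz2[j] = s / n
        delta_outer = 0.0
        while True:
            total_sweeps += 1
            dmax = 0.0
            # intercept update (unpenalized)
            num = 0.0
            for i in range(n):
                num += w[i] * r[i]
            d0 = num / wsum
            if d0 != 0.0:
                beta0 += d0
                for i in range(n):
                    r[i] -= d0
                if abs(d0) > dmax:
                    dmax = abs(d0)
            for j in range(p):
                if wz2[j] <= 0.0:
                    continue
                g = 0.0
                for i in range(n):
                    g += w[i] * Z[i, j] * r[i]
                g = g / n + wz2[j] * beta[j]
                bnew = _soft(g, lam) / wz2[j]
                d = bnew - beta[j]
                if d != 0.0:
                    beta[j] = bnew
                    for i in range(n):
                        r[i] -= d * Z[i, j]
                    if abs(d) > dmax:
                        dmax = abs(d)
            if dmax > delta_outer:
                delta_outer = dmax
            if dmax < tol or total_sweeps >= max_sweeps:
                break
        if delta_outer < tol:
            converged = True
            break
        if total_sweeps >= max_sweeps:
            break
    return beta0, beta, total_sweeps, converged


@njit(cache=True)
def fit_path_standardized(Z, y, lambdas, tol, max_sweeps):
    """Warm-started fits over a descending lambda grid.

    Returns (B0, B, sweeps, converged) with one row per grid value.
    """
    n, p = Z.shape
    L = lambdas.shape[0]
    B0 = np.empty(L)
    B = np.empty((L, p))
    sweeps = np.empty(L, dtype=np.int64)
    conv = np.empty(L, dtype=np.bool_)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    beta0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    for li in range(L):
        beta0, beta, s, c = fit_one_standardized(
            Z, y, lambdas[li], beta0, beta, tol, max_sweeps
        )
        B0[li] = beta0
        for j in range(p):
            B[li, j] = beta[j]
        sweeps[li] = s
        conv[li] = c
    return B0, B, sweeps, conv
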