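"""Block coordinate-descent graphical-lasso kernel.

Solves  max_K  log det K - tr(S K) - lambda * sum_{i != j} |K_ij|
by the classic column-wise algorithm: each column update is an L1-penalized
regression on the current covariance estimate W, solved by cyclic coordinate
descent with soft thresholding.  The lasso zero pattern is tracked in the
regression coefficients, so off-diagonal zeros of the returned precision
matrix are exact (bitwise 0.0), which downstream edge counting relies on.

The kernel is numba-compiled; warm starts (W, B carried across a penalty
path) make full EBIC paths and bootstrap loops cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _lasso_column(W11, s12, beta, lam, tol, max_sweeps):
    """Cyclic coordinate descent for 0.5 b'W11 b - s12'b + lam*|b|_1."""
    m = s12.shape[0]
    for _ in range(max_sweeps):
        delta = 0.0
        for k in range(m):
            old = beta[k]
            r = s12[k]
            for j in range(m):
                if j != k:
                    r -= W11[k, j] * beta[j]
            if r > lam:
                new = (r - lam) / W11[k, k]
            elif r < -lam:
                new = (r + lam) / W11[k, k]
            else:
                new = 0.0
            beta[k] = new
            d = abs(new - old)
            if d > delta:
                delta = d
        if delta < tol:
            break
    return beta


@njit(cache=False)
def glasso_kernel(S, lam, penalize_diagonal, tol, max_iter, W, B):
    """One glasso solve; W and B are warm-start state, modified in place.

    Returns (K, n_iter, converged).  K has exact zeros where the lasso
    coefficients are zero.
    """
    p = S.shape[0]
    # diagonal of W is fixed by the stationarity condition
    for i in range(p):
        W[i, i] = S[i, i] + (lam if penalize_diagonal else 0.0)

    W11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    beta = np.empty(p - 1)
    n_iter = 0
    converged = False
    inner_tol = tol * 0.1
    for it in range(max_iter):
        n_iter = it + 1
        max_change = 0.0
        for col in range(p):
            # gather the submatrix excluding row/col `col`
            a = 0
            for i in range(p):
                if i == col:
                    continue
                s12[a] = S[i, col]
                beta[a] = B[i, col]
                b = 0
                for j in range(p):
                    if j == col:
                        continue
                    W11[a, b] = W[i, j]
                    b += 1
                a += 1
            _lasso_column(W11, s12, beta, lam, inner_tol, 1000)
            # scatter back: w12 = W11 @ beta
            a = 0
            for i in range(p):
                if i == col:
                    continue
                B[i, col] = beta[a]
                w_new = 0.0
                for b in range(p - 1):
                    w_new += W11[a, b] * beta[b]
                change = abs(w_new - W[i, col])
                if change > max_change:
                    max_change = change
                W[i, col] = w_new
                W[col, i] = w_new
                a += 1
        if max_change < tol:
            converged = True
            break

    # recover K column-wise; zeros of beta give exact zeros of K
    K = np.zeros((p, p))
    for col in range(p):
        dot = 0.0
        for i in range(p):
            if i != col:
                dot += W[i, col] * B[i, col]
        k_cc = 1.0 / (W[col, col] - dot)
        K[col, col] = k_cc
        for i in range(p):
            if i != col and B[i, col] != 0.0:
                K[i, col] = -B[i, col] * k_cc
    # symmetrize, preserving the (symmetric-by-construction) zero pattern
    for i in range(p):
        for j in range(i + 1, p):
            if K[i, j] == 0.0 or K[j, i] == 0.0:
                K[i, j] = 0.0
                K[j, i] = 0.0
            else:
                v = 0.5 * (K[i, j] + K[j, i])
                K[i, j] = v
                K[j, i] = v
    return K, n_iter, converged


def dual_gap(S: np.ndarray, K: np.ndarray, lam: float) -> float:
    """Convex duality gap of the glasso objective at K (0 at the optimum)."""
    p = S.shape[0]
    gap = float(np.sum(S * K)) - p
    gap += lam * (np.abs(K).sum() - np.abs(np.diag(K)).sum())
    return abs(gap)
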