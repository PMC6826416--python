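"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library's own code paths: shortest paths and
betweenness are computed by exhaustive enumeration of simple paths, and
partial correlations by explicit least-squares residualization.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def enumerate_simple_paths(weights: np.ndarray, src: int, dst: int):
    """All simple paths src -> dst over nonzero edges, with their lengths."""
    p = weights.shape[0]
    out = []

    def extend(path, length):
        last = path[-1]
        if last == dst:
            out.append((list(path), length))
            return
        for nxt in range(p):
            if weights[last, nxt] != 0 and nxt not in path:
                path.append(nxt)
                extend(path, length + 1.0 / abs(weights[last, nxt]))
                path.pop()

    extend([src], 0.0)
    return out


def brute_distance_matrix(weights: np.ndarray) -> np.ndarray:
    p = weights.shape[0]
    d = np.full((p, p), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            paths = enumerate_simple_paths(weights, i, j)
            if paths:
                d[i, j] = min(length for _, length in paths)
    return d


def brute_closeness(weights: np.ndarray) -> np.ndarray:
    d = brute_distance_matrix(weights)
    p = weights.shape[0]
    c = np.zeros(p)
    for i in range(p):
        row = np.delete(d[i], i)
        finite = row[np.isfinite(row)]
        if finite.size and finite.sum() > 0:
            c[i] = 1.0 / finite.sum()
    return c


def brute_betweenness(weights: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Fractional-credit betweenness by enumerating all tied shortest paths."""
    p = weights.shape[0]
    b = np.zeros(p)
    for i in range(p):
        for j in range(i + 1, p):
            paths = enumerate_simple_paths(weights, i, j)
            if not paths:
                continue
            best = min(length for _, length in paths)
            shortest = [pth for pth, length in paths if length <= best + tol]
            for pth in shortest:
                for node in pth[1:-1]:
                    b[node] += 1.0 / len(shortest)
    return b


def residual_partial_correlations(cov: np.ndarray) -> np.ndarray:
    """Partial correlations by regression residualization at the population level.

    For each pair (i, j), residualize variables i and j on all remaining
    variables using the covariance algebra of least squares, then correlate
    the residuals.
    """
    p = cov.shape[0]
    out = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            rest = [k for k in range(p) if k not in (i, j)]
            if rest:
                C_rr = cov[np.ix_(rest, rest)]
                C_ir = cov[i, rest]
                C_jr = cov[j, rest]
                sol_i = np.linalg.solve(C_rr, C_ir)
                sol_j = np.linalg.solve(C_rr, C_jr)
                v_i = cov[i, i] - C_ir @ sol_i
                v_j = cov[j, j] - C_jr @ sol_j
                c_ij = cov[i, j] - C_ir @ sol_j
            else:
                v_i, v_j, c_ij = cov[i, i], cov[j, j], cov[i, j]
            out[i, j] = out[j, i] = c_ij / np.sqrt(v_i * v_j)
    return out


def random_correlation(p: int, rng: np.random.Generator, cond: float = 50.0) -> np.ndarray:
    """A random well-conditioned correlation matrix."""
    A = rng.normal(size=(p, p))
    C = A @ A.T + cond / 10.0 * np.eye(p)
    d = np.sqrt(np.diag(C))
    R = C / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0
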