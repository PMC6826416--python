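"""Regularized partial-correlation network estimation.

Pipeline: Pearson correlation matrix -> graphical-lasso penalty path ->
EBIC (gamma = 0.5 by default) model selection -> conversion of the selected
precision matrix to partial-correlation edge weights.  The EBIC follows the
Foygel-Drton Gaussian form

    EBIC = -n * [log det K - tr(S K)] + E log n + 4 E gamma log p

with E the number of nonzero upper-triangle off-diagonal entries of K.
Larger gamma favours sparser graphs; gamma = 0 recovers the ordinary BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._glasso import dual_gap, glasso_kernel
from .datasets import SubscaleMatrix

__all__ = [
    "CorrelationMatrix",
    "GlassoConfig",
    "PartialCorrelationNetwork",
    "GlassoConvergenceError",
    "correlation_matrix",
    "lambda_grid",
    "glasso_fit",
    "precision_to_partials",
    "ebic_score",
    "select_network",
]


class GlassoConvergenceError(RuntimeError):
    """Raised when the glasso solver exhausts its iteration cap."""

    def __init__(self, lam: float, gap: float, max_iter: int):
        self.lam = lam
        self.gap = gap
        super().__init__(
            f"glasso did not converge at lambda={lam:g} within {max_iter} "
            f"iterations (duality gap {gap:.3e})"
        )


@dataclass
class CorrelationMatrix:
    """A p x p Pearson correlation matrix together with the sample size."""

    S: np.ndarray
    n: int
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        p = self.S.shape[0]
        if self.S.shape != (p, p):
            raise ValueError("S must be square")
        if not np.allclose(self.S, self.S.T, atol=1e-12):
            raise ValueError("S must be symmetric")
        if not np.allclose(np.diag(self.S), 1.0):
            raise ValueError("S must have unit diagonal")

    @property
    def p(self) -> int:
        return self.S.shape[0]


@dataclass
class GlassoConfig:
    """Tuning parameters for the EBIC-glasso estimator.

    gamma : EBIC hyperparameter (0 = plain BIC; 0.5 is the conventional
        conservative choice for psychometric networks).
    n_lambda / lambda_min_ratio : geometry of the penalty path, from
        lambda_max = max off-diagonal |S_ij| down to lambda_max * ratio.
    penalize_diagonal : whether the L1 penalty also shrinks the precision
        diagonal (off by default; penalizing it deflates all partials).
    """

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    penalize_diagonal: bool = False
    solver_tol: float = 1e-7
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")


@dataclass
class PartialCorrelationNetwork:
    """The selected network: edge weights are regularized partial correlations."""

    weights: np.ndarray
    node_labels: list[str]
    lambda_selected: float
    ebic_selected: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        p = self.weights.shape[0]
        if self.weights.shape != (p, p):
            raise ValueError("weights must be square")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weights must have zero diagonal")
        if np.any(np.abs(self.weights) >= 1):
            raise ValueError("|weights| must be < 1")

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Nonzero edges as (node_i, node_j, weight) with i before j."""
        out = []
        p = self.p
        for i in range(p):
            for j in range(i + 1, p):
                w = self.weights[i, j]
                if w != 0.0:
                    out.append((self.node_labels[i], self.node_labels[j], float(w)))
        return out


def correlation_matrix(data: SubscaleMatrix) -> CorrelationMatrix:
    """Pearson product-moment correlations of the subscale columns."""
    x = data.values
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 subjects for correlations")
    sd = x.std(axis=0, ddof=1)
    dead = [data.node_labels[j] for j in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"zero-variance column(s): {', '.join(dead)}")
    S = np.corrcoef(x, rowvar=False)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    np.clip(S, -1.0, 1.0, out=S)
    return CorrelationMatrix(S=S, n=n, node_labels=list(data.node_labels))


def lambda_grid(S: CorrelationMatrix, config: GlassoConfig | None = None) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max = max offdiag |S_ij|."""
    config = config or GlassoConfig()
    if S.p < 2:
        raise ValueError("need p >= 2")
    iu = np.triu_indices(S.p, k=1)
    lam_max = float(np.max(np.abs(S.S[iu])))
    if lam_max == 0.0:
        warnings.warn("all off-diagonal correlations are zero; degenerate grid {0}")
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)


class _WarmState:
    """Mutable (W, B) state for warm-started path fitting."""

    def __init__(self, S: np.ndarray):
        self.W = S.copy()
        self.B = np.zeros_like(S)


def glasso_fit(
    S: CorrelationMatrix,
    lam: float,
    config: GlassoConfig | None = None,
    _warm: _WarmState | None = None,
) -> np.ndarray:
    """Solve the graphical lasso at a single penalty; returns the precision K.

    K maximizes  log det K - tr(S K) - lam * sum_{i!=j} |K_ij|  (the diagonal
    is additionally penalized when configured).  Off-diagonal zeros are exact.
    """
    config = config or GlassoConfig()
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    state = _warm or _WarmState(S.S)
    K, n_iter, converged = glasso_kernel(
        S.S,
        float(lam),
        config.penalize_diagonal,
        config.solver_tol,
        config.max_iter,
        state.W,
        state.B,
    )
    if not converged:
        raise GlassoConvergenceError(lam, dual_gap(S.S, K, lam), config.max_iter)
    return K


def precision_to_partials(K: np.ndarray) -> np.ndarray:
    """Convert a precision matrix to partial correlations.

    w_ij = -K_ij / sqrt(K_ii * K_jj); the diagonal is zero and exact zeros of
    K map to exact zeros of w.
    """
    K = np.asarray(K, dtype=float)
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    scale = np.sqrt(d)
    w = -K / np.outer(scale, scale)
    w[K == 0.0] = 0.0  # preserve exact sparsity through the division
    np.fill_diagonal(w, 0.0)
    return (w + w.T) / 2.0


def ebic_score(K: np.ndarray, S: CorrelationMatrix, n: int, gamma: float) -> float:
    """Extended BIC of a Gaussian graphical model estimate.

    E counts exactly-zero-free upper-triangle entries of K; the lasso yields
    exact zeros, so no numerical threshold is involved.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    K = np.asarray(K, dtype=float)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("K must be positive-definite")
    loglik = logdet - float(np.sum(S.S * K))
    p = K.shape[0]
    iu = np.triu_indices(p, k=1)
    E = int(np.count_nonzero(K[iu]))
    return -n * loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def _check_sample_size(n: int, p: int) -> None:
    if n < p + 1:
        raise ValueError(f"need n >= p + 1 subjects (got n={n}, p={p})")
    if n < 3 * p:
        warnings.warn(
            f"n={n} is below 3p={3 * p}; estimates may be unstable", stacklevel=3
        )


def select_network(
    data: SubscaleMatrix, config: GlassoConfig | None = None
) -> PartialCorrelationNetwork:
    """Fit the glasso along the penalty path and return the EBIC minimizer.

    Ties in EBIC are broken toward the larger penalty (sparser model).  The
    path is traversed from sparse to dense with warm starts.
    """
    config = config or GlassoConfig()
    _check_sample_size(data.n, data.p)
    S = correlation_matrix(data)
    grid = lambda_grid(S, config)
    state = _WarmState(S.S)
    best = None
    for lam in grid:
        K = glasso_fit(S, lam, config, _warm=state)
        score = ebic_score(K, S, S.n, config.gamma)
        if best is None or score < best[0]:  # strict: ties keep larger lambda
            best = (score, lam, K)
    score, lam, K = best
    return PartialCorrelationNetwork(
        weights=precision_to_partials(K),
        node_labels=list(data.node_labels),
        lambda_selected=float(lam),
        ebic_selected=float(score),
    )
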