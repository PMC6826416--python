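"""Bootstrap accuracy and stability diagnostics for estimated networks.

Two resampling schemes, both re-running the full EBIC-glasso estimator on
every replicate:

* nonparametric edge bootstrap — resample subjects with replacement and
  collect 95% quantile confidence intervals per edge weight;
* case-dropping bootstrap — re-estimate the network on subsamples retaining
  a decreasing fraction of subjects and correlate the recomputed centrality
  indices with the full-sample ones.  The correlation-stability (CS)
  coefficient is the largest drop proportion at which at least 95% of
  replicates (and of replicates at every smaller proportion) still correlate
  >= 0.7 with the original; values below 0.25 are conventionally considered
  unstable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import betweenness, closeness, strength
from .datasets import SubscaleMatrix
from .estimation import GlassoConfig, select_network

__all__ = [
    "EdgeBootstrapResult",
    "StabilityResult",
    "DEFAULT_DROP_GRID",
    "bootstrap_edges",
    "case_drop_bootstrap",
    "cs_coefficient",
]

logger = logging.getLogger(__name__)

DEFAULT_DROP_GRID = (0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75)

_INDICES = ("strength", "closeness", "betweenness")


@dataclass
class EdgeBootstrapResult:
    """Edge-weight bootstrap: observed weights, replicate draws, quantile CIs."""

    node_labels: list[str]
    observed: np.ndarray              # p x p observed weights
    replicates: np.ndarray            # n_boots x p x p replicate weights
    ci_level: float = 0.95

    @property
    def n_boots(self) -> int:
        return self.replicates.shape[0]

    def table(self) -> pd.DataFrame:
        """One row per node pair: observed, bootstrap mean, CI bounds."""
        lo_q = (1.0 - self.ci_level) / 2.0
        p = len(self.node_labels)
        rows = []
        for i in range(p):
            for j in range(i + 1, p):
                draws = self.replicates[:, i, j]
                rows.append(
                    {
                        "node_i": self.node_labels[i],
                        "node_j": self.node_labels[j],
                        "observed": self.observed[i, j],
                        "boot_mean": draws.mean(),
                        "ci_lower": np.quantile(draws, lo_q),
                        "ci_upper": np.quantile(draws, 1.0 - lo_q),
                    }
                )
        return pd.DataFrame(rows)

    def interval(self, label_i: str, label_j: str) -> tuple[float, float]:
        i = self.node_labels.index(label_i)
        j = self.node_labels.index(label_j)
        lo_q = (1.0 - self.ci_level) / 2.0
        draws = self.replicates[:, i, j]
        return float(np.quantile(draws, lo_q)), float(np.quantile(draws, 1.0 - lo_q))


@dataclass
class StabilityResult:
    """Case-dropping bootstrap output.

    ``correlations[index]`` is an (n_proportions, n_boots) array of Pearson
    correlations between replicate and original centralities; degenerate
    replicates (e.g. an empty selected network, giving a constant centrality
    vector) are recorded as correlation 0 and counted in
    ``n_degenerate[index]`` rather than dropped.
    """

    drop_proportions: np.ndarray
    correlations: dict[str, np.ndarray]
    n_degenerate: dict[str, int] = field(default_factory=dict)
    threshold_correlation: float = 0.7
    confidence_quantile: float = 0.95

    def cs(self, threshold: float | None = None, quantile: float | None = None) -> dict[str, float]:
        return cs_coefficient(
            self,
            threshold=self.threshold_correlation if threshold is None else threshold,
            quantile=self.confidence_quantile if quantile is None else quantile,
        )

    def table(self) -> pd.DataFrame:
        rows = []
        for index, mat in self.correlations.items():
            for qi, q in enumerate(self.drop_proportions):
                for rep in range(mat.shape[1]):
                    rows.append(
                        {
                            "index": index,
                            "proportion": q,
                            "replicate": rep,
                            "correlation": mat[qi, rep],
                        }
                    )
        return pd.DataFrame(rows)


def _centrality_vectors(net) -> dict[str, np.ndarray]:
    return {
        "strength": strength(net),
        "closeness": closeness(net),
        "betweenness": betweenness(net),
    }


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    """Pearson correlation, or None when either vector is constant."""
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def bootstrap_edges(
    data: SubscaleMatrix,
    config: GlassoConfig | None = None,
    n_boots: int = 2500,
    seed: int = 0,
    retry_cap: int = 100,
) -> EdgeBootstrapResult:
    """Nonparametric bootstrap of the edge weights.

    Subjects are resampled with replacement ``n_boots`` times and the full
    estimator re-run on each replicate.  Replicates that draw a zero-variance
    column are redrawn (logged) up to ``retry_cap`` consecutive retries.
    """
    config = config or GlassoConfig()
    rng = np.random.default_rng(seed)
    observed = select_network(data, config)
    n, p = data.n, data.p
    replicates = np.empty((n_boots, p, p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_boots):
            for attempt in range(retry_cap + 1):
                idx = rng.integers(0, n, size=n)
                sample = data.values[idx]
                if np.all(sample.std(axis=0) > 0):
                    break
                logger.info("bootstrap replicate %d redrawn (zero-variance column)", b)
            else:
                raise RuntimeError("exceeded retry cap for degenerate bootstrap draws")
            net = select_network(
                SubscaleMatrix(values=sample, node_labels=list(data.node_labels)),
                config,
            )
            replicates[b] = net.weights
    return EdgeBootstrapResult(
        node_labels=list(data.node_labels),
        observed=observed.weights,
        replicates=replicates,
    )


def case_drop_bootstrap(
    data: SubscaleMatrix,
    config: GlassoConfig | None = None,
    drop_proportions=DEFAULT_DROP_GRID,
    n_boots: int = 100,
    seed: int = 0,
    correlation: str = "pearson",
) -> StabilityResult:
    """Case-dropping (subset) bootstrap of the centrality indices.

    For each proportion q, ``n_boots`` subsamples of size round(n * (1 - q))
    are drawn without replacement; the network and its centralities are
    recomputed and correlated with the full-sample centralities.
    """
    config = config or GlassoConfig()
    grid = np.asarray(sorted(drop_proportions), dtype=float)
    if grid.size == 0:
        raise ValueError("drop_proportions must be non-empty")
    n, p = data.n, data.p
    sizes = np.round(n * (1.0 - grid)).astype(int)
    floor = p + 2
    bad = grid[sizes < floor]
    if bad.size:
        raise ValueError(
            f"drop proportion(s) {bad.tolist()} leave fewer than p + 2 = {floor} subjects"
        )
    if correlation not in ("pearson", "spearman"):
        raise ValueError("correlation must be 'pearson' or 'spearman'")

    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        original = _centrality_vectors(select_network(data, config))
        if correlation == "spearman":
            from scipy.stats import rankdata

            original = {k: rankdata(v) for k, v in original.items()}

        corrs = {idx: np.empty((grid.size, n_boots)) for idx in _INDICES}
        n_degenerate = {idx: 0 for idx in _INDICES}
        for qi, (q, m) in enumerate(zip(grid, sizes)):
            for b in range(n_boots):
                idx_rows = rng.permutation(n)[:m]
                sub = SubscaleMatrix(
                    values=data.values[idx_rows], node_labels=list(data.node_labels)
                )
                vecs = _centrality_vectors(select_network(sub, config))
                for index in _INDICES:
                    v = vecs[index]
                    if correlation == "spearman":
                        v = rankdata(v)
                    r = _safe_pearson(original[index], v)
                    if r is None:
                        n_degenerate[index] += 1
                        logger.info(
                            "degenerate %s replicate at q=%.2f recorded as 0", index, q
                        )
                        r = 0.0
                    corrs[index][qi, b] = r
    return StabilityResult(drop_proportions=grid, correlations=corrs, n_degenerate=n_degenerate)


def cs_coefficient(
    result: StabilityResult, threshold: float = 0.7, quantile: float = 0.95
) -> dict[str, float]:
    """Correlation-stability coefficient per centrality index.

    The largest drop proportion q such that, at q and at every smaller grid
    proportion, at least ``quantile`` of the replicates correlate >= threshold
    with the original centralities; 0 if no proportion qualifies.
    """
    grid = np.asarray(result.drop_proportions)
    if grid.size == 0:
        raise ValueError("empty drop-proportion grid")
    out = {}
    for index, mat in result.correlations.items():
        ok = (mat >= threshold).mean(axis=1) >= quantile
        cs = 0.0
        for qi in range(grid.size):
            if ok[qi]:
                cs = float(grid[qi])
            else:
                break
        out[index] = cs
    return out
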