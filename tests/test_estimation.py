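"""Network estimation: correlations, penalty grid, glasso, EBIC, selection."""

import warnings

import numpy as np
import pytest

from ednet.datasets import SubscaleMatrix, build_precision_from_partials, simulate_subscales
from ednet.estimation import (
    CorrelationMatrix,
    GlassoConfig,
    correlation_matrix,
    ebic_score,
    glasso_fit,
    lambda_grid,
    precision_to_partials,
    select_network,
)
from ._oracles import random_correlation, residual_partial_correlations


def _data(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"V{i}" for i in range(values.shape[1])]
    return SubscaleMatrix(values=values, node_labels=labels)


class TestCorrelationMatrix:
    def test_identical_columns_correlate_perfectly(self):
        x = np.random.default_rng(0).normal(size=20)
        S = correlation_matrix(_data(np.column_stack([x, x, -x])))
        assert S.S[0, 1] == pytest.approx(1.0)
        assert S.S[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_fixture(self):
        # 4 subjects, 2 variables; Pearson r computed by hand:
        # x = (1,2,3,4), y = (2,1,4,3): cov = 1, sd_x = sd_y = sqrt(5/3) -> r = 0.6
        S = correlation_matrix(_data([[1, 2], [2, 1], [3, 4], [4, 3]]))
        assert S.S[0, 1] == pytest.approx(0.6, abs=1e-12)

    def test_zero_variance_column_named_in_error(self):
        with pytest.raises(ValueError, match="V1"):
            correlation_matrix(_data([[1.0, 2.0], [2.0, 2.0], [3.0, 2.0]]))


class TestLambdaGrid:
    def test_geometric_spacing(self):
        S = CorrelationMatrix(S=np.array([[1, 0.5], [0.5, 1]]), n=50)
        grid = lambda_grid(S, GlassoConfig(n_lambda=3, lambda_min_ratio=0.01))
        assert np.allclose(grid, [0.5, 0.05, 0.005])

    def test_two_point_grid(self):
        S = CorrelationMatrix(S=np.array([[1, 0.3], [0.3, 1]]), n=50)
        grid = lambda_grid(S, GlassoConfig(n_lambda=2, lambda_min_ratio=0.1))
        assert np.allclose(grid, [0.3, 0.03])

    def test_identity_gives_degenerate_zero_grid(self):
        S = CorrelationMatrix(S=np.eye(3), n=50)
        with pytest.warns(UserWarning):
            grid = lambda_grid(S)
        assert grid.tolist() == [0.0]


class TestGlassoFit:
    def test_penalty_above_kkt_threshold_empties_network(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = int(rng.integers(3, 7))
            S = CorrelationMatrix(S=random_correlation(p, rng), n=100)
            lam = np.abs(S.S - np.eye(p)).max()
            K = glasso_fit(S, lam * 1.0001)
            assert np.count_nonzero(K - np.diag(np.diag(K))) == 0

    def test_unpenalized_fit_matches_matrix_inversion(self):
        rng = np.random.default_rng(2)
        S = CorrelationMatrix(S=random_correlation(5, rng), n=100)
        K = glasso_fit(S, 0.0)
        assert np.abs(K - np.linalg.inv(S.S)).max() <= 1e-6

    def test_two_node_soft_threshold_closed_form(self):
        S = CorrelationMatrix(S=np.array([[1, 0.5], [0.5, 1]]), n=100)
        K = glasso_fit(S, 0.2)
        W = np.linalg.inv(K)
        assert W[0, 1] == pytest.approx(0.3, abs=1e-9)
        assert np.allclose(K, np.linalg.inv([[1, 0.3], [0.3, 1]]), atol=1e-8)

    def test_agrees_with_sklearn_graphical_lasso(self):
        sklearn = pytest.importorskip("sklearn.covariance")
        rng = np.random.default_rng(3)
        cfg = GlassoConfig(solver_tol=1e-9, max_iter=5000)
        for _ in range(20):
            p = int(rng.integers(3, 8))
            S = CorrelationMatrix(S=random_correlation(p, rng), n=100)
            lam = float(rng.uniform(0.02, 0.3))
            K = glasso_fit(S, lam, cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, K_ref = sklearn.graphical_lasso(
                    S.S, alpha=lam, tol=1e-12, max_iter=5000, mode="lars"
                )
            assert np.abs(K - K_ref).max() <= 1e-4


class TestPrecisionToPartials:
    def test_identity_maps_to_zero(self):
        assert np.array_equal(precision_to_partials(np.eye(3)), np.zeros((3, 3)))

    def test_two_node_formula(self):
        w = precision_to_partials(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert w[0, 1] == pytest.approx(0.5)

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            K = np.linalg.inv(random_correlation(4, rng))
            w = precision_to_partials(K)
            oracle = residual_partial_correlations(np.linalg.inv(K))
            np.fill_diagonal(oracle, 0.0)
            assert np.abs(w - oracle).max() <= 1e-8

    def test_exact_zeros_preserved(self):
        K = np.eye(4)
        K[0, 1] = K[1, 0] = -0.3
        w = precision_to_partials(K)
        assert w[2, 3] == 0.0 and w[0, 2] == 0.0

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            precision_to_partials(np.array([[1.0, 0.0], [0.0, -2.0]]))


class TestEbicScore:
    def test_gamma_zero_reduces_to_bic(self):
        rng = np.random.default_rng(5)
        S = CorrelationMatrix(S=random_correlation(4, rng), n=60)
        K = np.linalg.inv(S.S)
        E = np.count_nonzero(K[np.triu_indices(4, 1)])
        sign, logdet = np.linalg.slogdet(K)
        L = logdet - np.sum(S.S * K)
        assert ebic_score(K, S, 60, gamma=0.0) == pytest.approx(-60 * L + E * np.log(60))

    def test_diagonal_precision_has_no_edge_penalty(self):
        S = CorrelationMatrix(S=np.eye(3), n=40)
        K = np.diag([2.0, 1.0, 0.5])
        L = np.log(np.prod([2.0, 1.0, 0.5])) - (2.0 + 1.0 + 0.5)
        assert ebic_score(K, S, 40, gamma=0.5) == pytest.approx(-40 * L)

    def test_worked_three_node_instance(self):
        # p = 3, E = 2, n = 84, gamma = 0.5; all three terms assembled by hand
        K = np.array([[1.2, -0.3, 0.0], [-0.3, 1.1, -0.2], [0.0, -0.2, 1.3]])
        S = CorrelationMatrix(
            S=np.array([[1.0, 0.4, 0.1], [0.4, 1.0, 0.3], [0.1, 0.3, 1.0]]), n=84
        )
        sign, logdet = np.linalg.slogdet(K)
        hand = (
            -84 * (logdet - float(np.sum(S.S * K)))
            + 2 * np.log(84)
            + 4 * 2 * 0.5 * np.log(3)
        )
        assert ebic_score(K, S, 84, gamma=0.5) == pytest.approx(hand, rel=1e-12)

    def test_non_pd_rejected(self):
        S = CorrelationMatrix(S=np.eye(2), n=10)
        with pytest.raises(ValueError):
            ebic_score(np.array([[1.0, 2.0], [2.0, 1.0]]), S, 10, 0.5)


class TestSelectNetwork:
    def test_independence_data_selects_empty_network(self):
        """Under a diagonal ground truth the selected model has no edges almost always."""
        labels = [f"V{i}" for i in range(5)]
        model = build_precision_from_partials([], labels)
        empty = 0
        for seed in range(100):
            data = simulate_subscales(model, n=500, seed=seed)
            if select_network(data).n_edges == 0:
                empty += 1
        assert empty >= 95

    def test_higher_gamma_is_sparser_in_aggregate(self):
        from ednet.datasets import reference_dataset

        wins = 0
        for seed in range(100):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                data = reference_dataset(n=84, seed=2000 + seed)
                e0 = select_network(data, GlassoConfig(gamma=0.0)).n_edges
                e5 = select_network(data, GlassoConfig(gamma=0.5)).n_edges
            wins += e5 <= e0
        assert wins >= 90

    def test_selected_weights_symmetric_zero_diagonal(self):
        from ednet.datasets import reference_dataset

        net = select_network(reference_dataset(n=200, seed=1))
        assert np.array_equal(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)
        iu = np.triu_indices(net.p, 1)
        assert net.n_edges == np.count_nonzero(net.weights[iu])

    def test_small_sample_warns_tiny_sample_errors(self):
        labels = [f"V{i}" for i in range(5)]
        model = build_precision_from_partials([], labels)
        with pytest.warns(UserWarning, match="below 3p"):
            select_network(simulate_subscales(model, n=10, seed=0))
        with pytest.raises(ValueError, match="p \\+ 1"):
            select_network(simulate_subscales(model, n=5, seed=0))
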