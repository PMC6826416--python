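"""Synthetic-data generator: precision construction, simulation, reference sample."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ednet.datasets import (
    CANONICAL_LABELS,
    REFERENCE_EDGES,
    GroundTruthModel,
    build_precision_from_partials,
    reference_dataset,
    reference_model,
    simulate_subscales,
)
from ._oracles import residual_partial_correlations


class TestBuildPrecision:
    def test_empty_edge_list_gives_identity(self):
        m = build_precision_from_partials([], ["A", "B", "C", "D"], diagonal=1.0)
        assert np.array_equal(m.precision, np.eye(4))
        assert np.array_equal(m.partials, np.zeros((4, 4)))

    def test_two_node_closed_form(self):
        m = build_precision_from_partials([("A", "B", 0.5)], ["A", "B"], diagonal=1.0)
        assert np.allclose(m.precision, [[1, -0.5], [-0.5, 1]])
        assert m.partials[0, 1] == pytest.approx(0.5)

    def test_reference_model_is_positive_definite_with_exact_partials(self):
        m = reference_model()
        assert np.linalg.eigvalsh(m.precision)[0] > 0
        assert not m.repaired
        # invert K independently and apply the standardization formula
        labels = list(m.node_labels)
        K = m.precision
        d = np.sqrt(np.diag(K))
        implied = -K / np.outer(d, d)
        for a, b, r in REFERENCE_EDGES:
            i, j = labels.index(a), labels.index(b)
            assert implied[i, j] == pytest.approx(r, abs=1e-12)

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_precision_from_partials(
                [("A", "B", 0.2), ("B", "A", 0.3)], ["A", "B", "C"]
            )

    def test_partial_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="partial"):
            build_precision_from_partials([("A", "B", 1.0)], ["A", "B"])

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            build_precision_from_partials([("A", "Z", 0.2)], ["A", "B"])

    def test_non_pd_edge_list_is_repaired_transparently(self):
        # an inconsistent triangle: three mutually positive partials of 0.9
        # cannot coexist (the raw K has smallest eigenvalue -0.8)
        edges = [("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.9)]
        m = build_precision_from_partials(edges, ["A", "B", "C"])
        assert m.repaired
        assert np.linalg.eigvalsh(m.precision)[0] >= 1e-3 - 1e-12
        assert m.requested_partials is not None
        assert m.requested_partials[0, 1] == pytest.approx(0.9)
        # achieved partials differ from requested after repair
        assert abs(m.partials[0, 1]) < 0.9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_partials_self_consistent_with_precision(self, seed):
        """Inverting the precision and standardizing reproduces the partials."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 8))
        labels = [f"V{i}" for i in range(p)]
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
        rng.shuffle(pairs)
        edges = [
            (labels[i], labels[j], rng.uniform(-0.45, 0.45))
            for i, j in pairs[: int(rng.integers(0, p))]
        ]
        m = build_precision_from_partials(edges, labels)
        oracle = residual_partial_correlations(np.linalg.inv(m.precision))
        np.fill_diagonal(oracle, 0.0)
        assert np.abs(m.partials - oracle).max() <= 1e-10


def test_model_json_round_trip(tmp_path):
    m = reference_model()
    path = tmp_path / "model.json"
    m.to_json(path, seed=3)
    back = GroundTruthModel.from_json(path)
    assert back.node_labels == list(m.node_labels)
    assert np.allclose(back.precision, m.precision)
    assert np.allclose(back.partials, m.partials)
    assert np.allclose(back.means, m.means)


class TestSimulate:
    def test_shape_and_labels(self):
        x = simulate_subscales(reference_model(), n=5, seed=1)
        assert x.values.shape == (5, 15)
        assert tuple(x.node_labels) == CANONICAL_LABELS

    def test_seeded_determinism(self):
        m = reference_model()
        a = simulate_subscales(m, n=40, seed=7)
        b = simulate_subscales(m, n=40, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_clipping_applies_after_rescaling(self):
        m = reference_model()
        x = simulate_subscales(m, n=500, seed=2, clip_to_range={"IA": (0.0, 30.0)})
        ia = x.column("IA")
        assert ia.min() >= 0.0 and ia.max() <= 30.0

    def test_large_n_recovers_true_partial_correlation(self):
        """Sample partial correlation of (OM, S) given the rest ~ the model's 0.42."""
        x = simulate_subscales(reference_model(), n=50_000, seed=11)
        cov = np.cov(x.values, rowvar=False)
        sample_partials = residual_partial_correlations(cov)
        labels = list(x.node_labels)
        i, j = labels.index("OM"), labels.index("S")
        assert sample_partials[i, j] == pytest.approx(0.42, abs=0.02)

    def test_sample_covariance_converges_in_n(self):
        m = reference_model()
        true_cov = np.diag(m.sds) @ m.correlation() @ np.diag(m.sds)
        errs = []
        for k, n in enumerate((100, 1_000, 10_000)):
            x = simulate_subscales(m, n=n, seed=100 + k)
            errs.append(np.linalg.norm(np.cov(x.values, rowvar=False) - true_cov))
        assert errs[0] > errs[1] > errs[2]

    def test_unclipped_marginals_are_gaussian(self):
        from scipy.stats import skew

        x = simulate_subscales(reference_model(), n=50_000, seed=13)
        assert np.abs(skew(x.values, axis=0)).max() < 0.05

    def test_non_pd_model_rejected_at_construction(self):
        with pytest.raises(ValueError, match="positive-definite"):
            GroundTruthModel(
                node_labels=["A", "B"],
                precision=np.array([[1.0, 2.0], [2.0, 1.0]]),
                partials=np.zeros((2, 2)),
                means=np.zeros(2),
                sds=np.ones(2),
            )


class TestReferenceDataset:
    def test_marginal_moments_match_published_table(self):
        x = reference_dataset(n=100_000, seed=3)
        ia = x.column("IA")
        assert ia.mean() == pytest.approx(12.60, abs=0.1)
        assert ia.std(ddof=1) == pytest.approx(8.37, abs=0.1)
        assert x.column("EB").mean() == pytest.approx(1.91, abs=0.05)

    def test_determinism(self):
        a = reference_dataset(n=84, seed=5)
        b = reference_dataset(n=84, seed=5)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.group, b.group)

    def test_group_sizes_and_bulimia_shift(self):
        x = reference_dataset(n=84, seed=4)
        assert (x.group == "restricting").sum() == 57
        assert (x.group == "binge_purging").sum() == 27
        bu = x.column("BU")
        assert bu[x.group == "binge_purging"].mean() > bu[x.group == "restricting"].mean()
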