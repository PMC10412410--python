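import numpy as np
import pytest
from sklearn.metrics import silhouette_samples as sk_silhouette

from oracles import silhouette_naive
from conftest import random_instance
from rareclust.errors import DomainError
from rareclust.preprocess import Embedding
from rareclust.silhouette import (
    ClusterLabels,
    cluster_coefficients,
    cosine_distance,
    pairwise_distances,
    silhouette_samples,
)


def _embedding(coords):
    coords = np.asarray(coords, dtype=float)
    ids = np.array([f"c{i}" for i in range(len(coords))], dtype=object)
    return Embedding(coords, ids)


class TestCosineDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1, 2, 3), (2, 4, 6), 0.0),  # parallel
            ((1, 0), (0, 1), 1.0),  # orthogonal
            ((1, 0), (-1, 0), 2.0),  # antiparallel
        ],
    )
    def test_reference_points(self, a, b, expected):
        assert cosine_distance(np.array(a), np.array(b)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_symmetry_and_self_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=(2, 7))
            assert cosine_distance(a, b) == pytest.approx(
                cosine_distance(b, a), abs=1e-12
            )
            assert cosine_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_zero_vector_is_domain_error(self):
        with pytest.raises(DomainError):
            cosine_distance(np.zeros(3), np.ones(3))


class TestPairwiseDistances:
    def test_matches_elementwise_calls(self):
        rng = np.random.default_rng(1)
        emb = _embedding(rng.normal(size=(9, 4)))
        full = pairwise_distances(emb, block_size=4)
        for i in range(9):
            for j in range(9):
                expected = (
                    0.0 if i == j
                    else cosine_distance(emb.coords[i], emb.coords[j])
                )
                assert full[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_with_duplicated_row(self):
        coords = np.array([[1.0, 2.0], [3.0, 1.0], [1.0, 2.0]])
        d = pairwise_distances(_embedding(coords))
        assert np.allclose(d, d.T, atol=1e-12)
        assert d[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_row_names_the_cell(self):
        coords = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(DomainError, match="c1"):
            pairwise_distances(_embedding(coords))


class TestSilhouetteSamples:
    def test_agrees_with_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            emb, labels = random_instance(rng)
            report = silhouette_samples(emb, labels)
            oracle = silhouette_naive(emb.coords, labels.labels)
            np.testing.assert_allclose(report.a, oracle["a"], atol=1e-10)
            np.testing.assert_allclose(report.b, oracle["b"], atol=1e-10)
            np.testing.assert_allclose(report.s, oracle["s"], atol=1e-10)

    def test_agrees_with_sklearn_cosine_silhouette(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            emb, labels = random_instance(rng)
            report = silhouette_samples(emb, labels)
            expected = sk_silhouette(
                emb.coords, labels.labels.astype(str), metric="cosine"
            )
            np.testing.assert_allclose(report.s, expected, atol=1e-8)

    def test_two_far_clusters_score_high(self):
        rng = np.random.default_rng(3)
        a = rng.normal(scale=0.1, size=(30, 3)) + np.array([10.0, 0, 0])
        b = rng.normal(scale=0.1, size=(30, 3)) + np.array([0, 10.0, 0])
        emb = _embedding(np.vstack([a, b]))
        labels = ClusterLabels(
            np.repeat(["A", "B"], 30), emb.cell_ids
        )
        report = silhouette_samples(emb, labels)
        assert (report.s > 0.9).all()

    def test_equidistant_cell_scores_zero(self):
        # c0 is angularly equidistant to its own partner and to cluster B
        coords = np.array([[1.0, 1.0], [2.0, 0.0], [0.0, 2.0]])
        labels = ClusterLabels(
            np.array(["A", "A", "B"], dtype=object),
            np.array(["c0", "c1", "c2"], dtype=object),
        )
        report = silhouette_samples(_embedding(coords), labels)
        assert report.s[0] == pytest.approx(0.0, abs=1e-12)

    def test_bounds_and_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        emb, labels = random_instance(rng)
        report = silhouette_samples(emb, labels)
        assert np.all(report.s >= -1.0) and np.all(report.s <= 1.0)
        perm = rng.permutation(emb.n_cells)
        permuted = silhouette_samples(
            Embedding(emb.coords[perm], emb.cell_ids[perm]),
            ClusterLabels(labels.labels[perm], labels.cell_ids[perm]),
        )
        np.testing.assert_allclose(permuted.s, report.s[perm], atol=1e-10)

    def test_single_cluster_is_domain_error(self):
        emb = _embedding(np.random.default_rng(0).normal(size=(5, 3)))
        labels = ClusterLabels(np.repeat("A", 5), emb.cell_ids)
        with pytest.raises(DomainError):
            silhouette_samples(emb, labels)

    def test_singleton_cluster_gets_zero(self):
        coords = np.array([[1.0, 0.1], [1.0, 0.2], [0.1, 1.0]])
        labels = ClusterLabels(
            np.array(["A", "A", "B"], dtype=object),
            np.array(["c0", "c1", "c2"], dtype=object),
        )
        report = silhouette_samples(_embedding(coords), labels)
        assert report.s[2] == 0.0 and report.a[2] == 0.0

    def test_separation_monotonicity(self):
        """Moving two clusters farther apart raises both coefficients."""
        rng = np.random.default_rng(5)
        base = rng.normal(scale=0.5, size=(40, 3))
        labels = ClusterLabels(
            np.repeat(["A", "B"], 20),
            np.array([f"c{i}" for i in range(40)], dtype=object),
        )
        prev = None
        for gap in (2.0, 5.0, 20.0):
            coords = base.copy() + 1.0
            coords[20:, 0] += gap
            rep = silhouette_samples(_embedding(coords), labels)
            coef = (
                cluster_coefficients(rep).set_index("cluster")["coef"]
            )
            if prev is not None:
                assert coef["A"] > prev["A"] and coef["B"] > prev["B"]
            prev = coef

    def test_subsampled_estimate_close_to_exact(self):
        rng = np.random.default_rng(6)
        emb, labels = random_instance(rng, n_max=100)
        exact = silhouette_samples(emb, labels)
        sub = silhouette_samples(
            emb, labels, subsample_cap=emb.n_cells // 2,
            min_per_cluster=5, seed=0,
        )
        scored = ~np.isnan(sub.s)
        assert scored.sum() >= emb.n_cells // 3
        # scored cells agree in sign/scale with the exact run on average
        assert abs(np.nanmean(sub.s) - exact.s.mean()) < 0.25


class TestClusterCoefficients:
    def test_hand_computed_mean_and_median(self):
        from rareclust.silhouette import SilhouetteReport

        ids = np.array(["c0", "c1", "c2"], dtype=object)
        labels = np.array(["X", "X", "X"], dtype=object)
        rep = SilhouetteReport(
            ids, labels, np.zeros(3), np.zeros(3),
            np.array([0.2, 0.4, 0.9]),
        )
        out = cluster_coefficients(rep).set_index("cluster")
        assert out.loc["X", "coef"] == pytest.approx(0.5)
        assert out.loc["X", "median"] == pytest.approx(0.4)

    def test_matches_group_mean_oracle(self):
        rng = np.random.default_rng(7)
        emb, labels = random_instance(rng)
        rep = silhouette_samples(emb, labels)
        out = cluster_coefficients(rep, labels).set_index("cluster")
        for c in set(labels.labels.astype(str)):
            members = labels.labels.astype(str) == c
            assert out.loc[c, "coef"] == pytest.approx(
                float(rep.s[members].mean()), abs=1e-12
            )
            assert out.loc[c, "n"] == int(members.sum())
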