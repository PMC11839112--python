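"""Metric suite: trivial identities, constructed cases, brute-force parity."""

import numpy as np
import pytest

from _oracles import (
    basw_oracle,
    clisi_oracle,
    gc_oracle,
    nmi_oracle,
    silhouette_oracle,
)
from peakgene.metrics import (
    batch_integration_metrics,
    bio_conservation_metrics,
    classification_metrics,
    clustering_nmi,
    knn_graph,
    pca_baseline,
    regression_metrics,
)


def three_blobs(n_per=20, sep=50.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(scale=0.3, size=(n_per, 2)) + [i * sep, 0]
                   for i in range(3)])
    y = np.repeat([0, 1, 2], n_per)
    b = np.tile([0, 1], len(X) // 2 + 1)[: len(X)]
    return X, y, b


class TestNMI:
    def test_identical_labelings_give_one(self):
        y = np.repeat([0, 1, 2], 10)
        assert clustering_nmi(y, y) == pytest.approx(1.0)

    def test_single_cluster_gives_zero(self):
        y = np.repeat([0, 1, 2], 10)
        assert clustering_nmi(y, np.zeros_like(y)) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_contingency_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 50)
        b = rng.integers(0, 3, 50)
        assert clustering_nmi(a, b) == pytest.approx(nmi_oracle(a, b), abs=1e-9)


class TestBioConservation:
    def test_separated_blobs_scored_as_perfectly_conserved(self):
        X, y, b = three_blobs()
        rep = bio_conservation_metrics(X, y, b, k=10)
        assert rep["NMI"] == pytest.approx(1.0)
        assert rep["cLISI"] == pytest.approx(1.0)
        assert rep["cASW"] > 0.9
        assert rep["ISO"] > 0.9

    def test_kmeans_fallback_matches_on_blobs(self):
        X, y, b = three_blobs(seed=3)
        rep = bio_conservation_metrics(X, y, b, k=10, clustering="kmeans")
        assert rep["NMI"] == pytest.approx(1.0)

    def test_single_cell_type_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError, match="2 cell types"):
            bio_conservation_metrics(X, np.zeros(20), np.tile([0, 1], 10))

    @pytest.mark.parametrize("seed", range(3))
    def test_casw_and_clisi_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 3, 40)
        b = rng.integers(0, 2, 40)
        rep = bio_conservation_metrics(X, y, b, k=7, clustering="kmeans")
        casw_ref = (silhouette_oracle(X, y).mean() + 1) / 2
        assert rep["cASW"] == pytest.approx(casw_ref, abs=1e-9)
        assert rep["cLISI"] == pytest.approx(clisi_oracle(X, y, 7), abs=1e-9)


class TestBatchIntegration:
    def test_connected_types_and_interleaved_batches(self):
        # each batch holds a near-duplicate copy of every point, so the
        # batch silhouette approaches 0 and bASW approaches 1
        rng = np.random.default_rng(1)
        base = np.vstack([rng.normal(scale=0.3, size=(15, 2)) + [i * 50, 0]
                          for i in range(3)])
        X = np.vstack([base, base + 1e-4])
        y = np.tile(np.repeat([0, 1, 2], 15), 2)
        b = np.r_[np.zeros(45, int), np.ones(45, int)]
        rep = batch_integration_metrics(X, y, b, k=10)
        assert rep["GC"] == pytest.approx(1.0)
        assert rep["bASW"] > 0.9

    def test_split_type_gc_term(self):
        """A type split 30/10 across disconnected islands scores 0.75."""
        rng = np.random.default_rng(2)
        far = np.array([0.0, 1000.0])
        X = np.vstack([
            rng.normal(scale=0.1, size=(30, 2)),              # type 0, island A
            rng.normal(scale=0.1, size=(10, 2)) + far,        # type 0, island B
            rng.normal(scale=0.1, size=(20, 2)) + 2 * far,    # type 1
        ])
        y = np.r_[np.zeros(40, int), np.ones(20, int)]
        b = np.tile([0, 1], 30)
        rep = batch_integration_metrics(X, y, b, k=5)
        assert rep["GC"] == pytest.approx((0.75 + 1.0) / 2)

    def test_single_batch_rejected(self):
        X = np.random.default_rng(3).normal(size=(20, 2))
        with pytest.raises(ValueError, match="2 batches"):
            batch_integration_metrics(X, np.tile([0, 1], 10), np.zeros(20))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed + 10)
        X = rng.normal(size=(45, 3))
        y = rng.integers(0, 3, 45)
        b = rng.integers(0, 2, 45)
        rep = batch_integration_metrics(X, y, b, k=6)
        assert rep["bASW"] == pytest.approx(basw_oracle(X, y, b), abs=1e-9)
        assert rep["GC"] == pytest.approx(gc_oracle(X, y, 6), abs=1e-9)

    def test_knn_graph_symmetric_no_selfloops(self):
        X = np.random.default_rng(4).normal(size=(25, 2))
        adj = knn_graph(X, k=5)
        assert (adj != adj.T).nnz == 0
        assert adj.diagonal().sum() == 0


class TestClassification:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 1, 0])
        scores = np.eye(3)[y] * 0.94 + 0.02
        rep = classification_metrics(y, scores)
        assert all(rep[m] == pytest.approx(1.0)
                   for m in ("ACC", "MacroF1", "MicroF1", "ROC-AUC"))

    def test_micro_f1_equals_accuracy_multiclass(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 4, 60)
        scores = rng.dirichlet(np.ones(4), size=60)
        rep = classification_metrics(y, scores)
        assert rep["MicroF1"] == pytest.approx(rep["ACC"], abs=1e-12)

    def test_hand_computed_confusion_pattern(self):
        """y=[0,0,0,1,1,2] vs pred=[0,1,0,1,2,2]: metrics enumerated by hand."""
        y = np.array([0, 0, 0, 1, 1, 2])
        pred = np.array([0, 1, 0, 1, 2, 2])
        scores = np.full((6, 3), 0.1)
        scores[np.arange(6), pred] = 0.8
        rep = classification_metrics(y, scores)
        assert rep["ACC"] == pytest.approx(4 / 6)
        # per-class F1: 0.8, 0.5, 2/3 (TP/FP/FN counted by hand)
        assert rep["MacroF1"] == pytest.approx((0.8 + 0.5 + 2 / 3) / 3)
        assert rep["MicroF1"] == pytest.approx(4 / 6)
        # one-vs-rest AUCs with ties at 0.5: 7.5/9, 5/8, 4.5/5
        assert rep["ROC-AUC"] == pytest.approx((7.5 / 9 + 5 / 8 + 4.5 / 5) / 3)

    def test_unnormalized_scores_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            classification_metrics(np.array([0, 1]), np.array([[0.9, 0.9], [0.1, 0.1]]))


class TestRegression:
    def test_identity_and_reversed_ranks(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        rep = regression_metrics(v, v)
        assert (rep["MSE"], rep["SRCC"], rep["PRCC"]) == (0.0, 1.0, 1.0)
        assert regression_metrics(v, v[::-1])["SRCC"] == pytest.approx(-1.0)

    def test_toy_vectors_match_direct_arithmetic(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        p = np.array([2.0, 2.0, 4.0, 3.0])
        rep = regression_metrics(t, p)
        assert rep["MSE"] == pytest.approx(0.75)

        def pearson(a, b):
            a, b = a - a.mean(), b - b.mean()
            return (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())

        assert rep["PRCC"] == pytest.approx(pearson(t, p), abs=1e-12)
        ranks_p = np.array([1.5, 1.5, 4.0, 3.0])   # average ranks for the tie
        assert rep["SRCC"] == pytest.approx(pearson(np.arange(1.0, 5.0), ranks_p),
                                            abs=1e-12)

    def test_zero_variance_reports_nan_not_zero(self):
        rep = regression_metrics(np.ones(5), np.arange(5.0))
        assert np.isnan(rep["SRCC"]) and np.isnan(rep["PRCC"])


class TestPCABaseline:
    def test_rank_one_matrix_fully_explained_by_first_component(self):
        u = np.arange(1.0, 11.0)[:, None]
        X = u @ np.ones((1, 8))
        scores = pca_baseline(X, n_components=3)
        assert np.allclose(scores[:, 1:], 0, atol=1e-9)

    def test_scores_are_orthogonal(self):
        X = np.random.default_rng(6).random((20, 15))
        scores = pca_baseline(X, n_components=5)
        gram = scores.T @ scores
        assert np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)

    def test_reconstruction_matches_full_svd_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.random((10, 8))
        scores = pca_baseline(X, n_components=4)
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        assert np.allclose(np.abs(scores), np.abs(U[:, :4] * S[:4]), atol=1e-9)


class TestRangeFuzz:
    def test_bounded_metrics_stay_in_unit_interval(self):
        """Randomized inputs never push any [0,1] metric out of range."""
        rng = np.random.default_rng(8)
        for _ in range(1000):
            n = int(rng.integers(12, 24))
            X = rng.normal(size=(n, 2)) * rng.uniform(0.1, 10)
            y = rng.integers(0, 3, n)
            b = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2 or len(np.unique(b)) < 2:
                continue
            rep = bio_conservation_metrics(X, y, b, k=5, clustering="kmeans")
            rep.update(batch_integration_metrics(X, y, b, k=5))
            for name, v in rep.items():
                assert 0.0 - 1e-12 <= v <= 1.0 + 1e-12, (name, v)
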