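"""Representation analyses: reconstruction error, PCA, K-means, agreement."""

import numpy as np
import pytest

from catperc import analysis as an
from catperc import perceptual as pc


class TestReconstructionError:
    def test_perfect_reconstruction_scores_zero(self, retinas):
        assert an.mse_error(retinas, retinas) == 0.0

    def test_half_guess_on_binary_data_scores_quarter(self, retinas):
        assert an.mse_error(np.full_like(retinas, 0.5), retinas) == pytest.approx(0.25)

    def test_zero_weight_dbn_scores_quarter(self, retinas):
        rbm1 = pc.RbmLayer(np.zeros((8, retinas.shape[1])), np.zeros(retinas.shape[1]),
                           np.zeros(8), use_bias=False)
        rbm2 = pc.RbmLayer(np.zeros((4, 8)), np.zeros(8), np.zeros(4), use_bias=False)
        dbn = pc.Dbn(rbm1, rbm2, rbm1_pretrained=True)
        assert an.reconstruction_error(dbn, retinas) == pytest.approx(0.25)

    def test_shape_mismatch_rejected(self, retinas):
        with pytest.raises(ValueError):
            an.mse_error(retinas[:3], retinas[:4])


class TestPca2:
    def test_centred_projection(self):
        X = np.random.default_rng(0).normal(size=(64, 10))
        coords = an.pca2(X)
        assert coords.shape == (64, 2)
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-10)

    def test_component_variance_ordering(self):
        X = np.random.default_rng(1).normal(size=(50, 6)) * np.array([5, 3, 1, 1, 1, 1])
        coords = an.pca2(X)
        assert coords[:, 0].var() >= coords[:, 1].var()

    def test_two_distinct_rows_collapse_to_two_points(self):
        a, b = np.zeros(5), np.ones(5)
        X = np.vstack([a] * 40 + [b] * 24)
        coords = an.pca2(X)
        assert len(np.unique(np.round(coords, 9), axis=0)) == 2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            an.pca2(np.ones((10, 4)))

    def test_sign_convention_is_reproducible(self):
        X = np.random.default_rng(2).normal(size=(30, 8))
        assert np.array_equal(an.pca2(X), an.pca2(X.copy()))


class TestKmeans4:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(3)
        centres = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
        truth = np.repeat(np.arange(4), 16)
        pts = centres[truth] + 0.1 * rng.normal(size=(64, 2))
        report = an.kmeans4(pts, seed=0)
        assert an.category_agreement(report.labels, truth) == 1.0
        assert report.empty_clusters == 0
        assert np.all(report.radii < 1.0)

    def test_degenerate_identical_points(self):
        report = an.kmeans4(np.zeros((64, 2)), seed=0)
        assert report.sizes.max() >= 62
        assert report.empty_clusters >= 3

    def test_seeded_replay_identical(self):
        pts = np.random.default_rng(4).normal(size=(64, 2))
        a = an.kmeans4(pts, seed=7)
        b = an.kmeans4(pts, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centroids, b.centroids)


class TestCategoryAgreement:
    def test_relabelled_partition_scores_one(self):
        cats = np.repeat(np.arange(4), 16)
        relabelled = (cats + 2) % 4
        assert an.category_agreement(relabelled, cats) == 1.0

    def test_single_swap_costs_one_item(self):
        cats = np.repeat(np.arange(4), 16)
        labels = cats.copy()
        labels[0] = 1
        assert an.category_agreement(labels, cats) == pytest.approx(63 / 64)

    def test_random_labels_score_near_chance(self):
        cats = np.repeat(np.arange(4), 16)
        rng = np.random.default_rng(5)
        scores = [an.category_agreement(rng.integers(0, 4, 64), cats) for _ in range(200)]
        assert 0.25 <= np.mean(scores) <= 0.45

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            an.category_agreement(np.zeros(10, dtype=int), np.zeros(9, dtype=int))


class TestLevelErrorCorrelation:
    def test_strictly_increasing_errors_give_unit_correlation(self):
        assert an.level_error_correlation([0, 1, 2, 3, 4], [0.1, 0.2, 0.3, 0.5, 0.9]) == pytest.approx(1.0, abs=0.15)
        assert an.level_error_correlation([0, 1, 2], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_constant_errors_rejected(self):
        with pytest.raises(ValueError):
            an.level_error_correlation([0, 1, 2], [0.5, 0.5, 0.5])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            an.level_error_correlation([0, 1], [0.1, 0.2])


def test_analyse_dbn_pipeline_is_deterministic(retinas, labels, fast_rbm1):
    rbm2 = pc.RbmLayer.init(fast_rbm1.hidden_size, 6, np.random.default_rng(0), use_bias=False)
    dbn = pc.Dbn(fast_rbm1.copy(), rbm2, rbm1_pretrained=True)
    a = an.analyse_dbn(dbn, retinas, labels[:, 0], seed=1)
    b = an.analyse_dbn(dbn, retinas, labels[:, 0], seed=1)
    assert np.array_equal(a.labels, b.labels)
    assert a.agreement == b.agreement
    assert 0.0 <= a.agreement <= 1.0
    assert -1.0 <= a.ari <= 1.0
    assert a.extras["reconstruction_error"] >= 0.0
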