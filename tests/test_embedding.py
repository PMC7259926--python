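"""Bandwidth calibration, KL divergence and embedding contracts."""

import numpy as np
import pytest

import ecoprov as ep
from ecoprov.embedding import _joint_q

from _oracles import bisect_sigma, kl_double_loop


def _simplex4(scale=1.0, dim=3):
    """Four pairwise-equidistant points (regular tetrahedron), padded to dim."""
    pts = np.array([
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]) * scale
    if dim > 3:
        pts = np.hstack([pts, np.zeros((4, dim - 3))])
    return pts


class TestCalibrateBandwidths:
    def test_equidistant_points_give_uniform_rows(self):
        X = _simplex4(dim=11)
        cond = ep.calibrate_bandwidths(X, perplexity=3.0)
        np.testing.assert_allclose(cond.P, (np.ones((4, 4)) - np.eye(4)) / 3.0,
                                   atol=1e-9)

    def test_rows_stochastic_with_zero_diagonal(self, rng):
        X = rng.normal(size=(40, 11))
        cond = ep.calibrate_bandwidths(X, perplexity=10.0)
        np.testing.assert_allclose(cond.P.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(np.diag(cond.P) == 0.0)

    def test_perplexity_calibrated_within_tolerance(self, rng):
        X = rng.normal(size=(60, 11))
        cond = ep.calibrate_bandwidths(X, perplexity=15.0)
        assert np.max(np.abs(cond.achieved_perplexity() - 15.0)) < 1e-4

    def test_sigma_matches_independent_bisection(self):
        # perplexity 3 keeps every root unique (at 2, interior points of the
        # line have an entropy plateau at log 2 from their two tied nearest
        # neighbours, so any sufficiently small sigma attains the target)
        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        cond = ep.calibrate_bandwidths(X, perplexity=3.0)
        for i in range(5):
            d2 = np.delete(((X - X[i]) ** 2).sum(axis=1), i)
            sigma_ref = bisect_sigma(d2, 3.0)
            assert abs(cond.sigma[i] - sigma_ref) < 1e-6

    def test_symmetrized_sums_to_one(self, rng):
        X = rng.normal(size=(30, 5))
        cond = ep.calibrate_bandwidths(X, perplexity=8.0)
        assert abs(cond.symmetrized().sum() - 1.0) < 1e-10

    def test_perplexity_at_least_n_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ep.ValidationError):
            ep.calibrate_bandwidths(X, perplexity=10.0)


class TestKLDivergence:
    def test_matched_distributions_give_zero(self):
        # equidistant points in both spaces -> P and Q both uniform
        X = _simplex4(dim=11)
        Y = _simplex4(scale=0.37)
        cond = ep.calibrate_bandwidths(X, perplexity=3.0)
        assert abs(ep.kl_divergence(cond, Y)) < 1e-12

    def test_nonnegative(self, rng):
        X = rng.normal(size=(25, 11))
        Y = rng.normal(size=(25, 3))
        cond = ep.calibrate_bandwidths(X, perplexity=5.0)
        assert ep.kl_divergence(cond, Y) >= 0.0

    def test_four_point_toy_matches_double_loop(self, rng):
        X = rng.normal(size=(4, 6))
        Y = rng.normal(size=(4, 3))
        cond = ep.calibrate_bandwidths(X, perplexity=2.0)
        P = cond.symmetrized()
        assert abs(ep.kl_divergence(cond, Y) - kl_double_loop(P, Y)) < 1e-12


class TestEmbed:
    def test_separated_blobs_stay_separated(self, rng):
        a = rng.normal(0.0, 0.3, size=(60, 11))
        b = rng.normal(0.0, 0.3, size=(60, 11)) + 8.0
        X = np.vstack([a, b])
        emb = ep.embed(X, perplexity=20, n_iter=300, seed=3)
        Ya, Yb = emb.Y[:60], emb.Y[60:]
        centroid_dist = np.linalg.norm(Ya.mean(axis=0) - Yb.mean(axis=0))
        spread = np.mean([
            np.linalg.norm(Ya - Ya.mean(axis=0), axis=1).mean(),
            np.linalg.norm(Yb - Yb.mean(axis=0), axis=1).mean(),
        ])
        assert centroid_dist > 5.0 * spread

    def test_same_seed_bit_identical(self, rng):
        X = rng.normal(size=(50, 11))
        a = ep.embed(X, perplexity=10, n_iter=100, seed=7)
        b = ep.embed(X, perplexity=10, n_iter=100, seed=7)
        assert np.array_equal(a.Y, b.Y)
        assert a.kl_final == b.kl_final

    def test_kl_trace_decreases_end_to_end(self, rng):
        X = rng.normal(size=(80, 11))
        X[:40] += 4.0
        emb = ep.embed(X, perplexity=15, n_iter=300, seed=5)
        assert emb.kl_trace is not None and len(emb.kl_trace) == 300
        assert emb.kl_trace[-1] <= emb.kl_trace[0]
        assert emb.kl_final == emb.kl_trace[-1] >= 0.0

    def test_permutation_equivariance_with_shared_init(self, rng):
        X = rng.normal(size=(30, 11))
        init = rng.normal(0, 1e-4, size=(30, 3))
        perm = rng.permutation(30)
        a = ep.embed(X, perplexity=8, n_iter=50, seed=0, init=init)
        b = ep.embed(X[perm], perplexity=8, n_iter=50, seed=0, init=init[perm])
        np.testing.assert_allclose(a.Y[perm], b.Y, rtol=1e-8, atol=1e-10)

    def test_knn_label_agreement_on_clean_field(self):
        spec = ep.SyntheticSpec(n_lat=12, n_lon=24, n_provinces=3, noise_sd=0.0,
                                low_biomass_frac=0.0, seed=4)
        field = ep.generate_field(spec)
        fm = ep.transform_features(ep.apply_masks(field))
        # zero noise duplicates every within-province row, which bounds the
        # row entropy below at log(province size); the perplexity must sit
        # above that bound to be reachable
        emb = ep.embed(fm, perplexity=100, n_iter=300, seed=1)
        truth = field.true_labels.reshape(-1)[fm.cell_ids]
        from sklearn.neighbors import KNeighborsClassifier

        knn = KNeighborsClassifier(n_neighbors=5)
        knn.fit(emb.Y, truth)
        assert knn.score(emb.Y, truth) >= 0.95

    def test_invalid_inputs_rejected(self, small_features):
        with pytest.raises(ep.ValidationError):
            ep.embed(small_features, perplexity=10, n_iter=0, seed=1)
        raw = ep.FeatureMatrix(values=small_features.values,
                               index_map=small_features.index_map, stage="raw11")
        with pytest.raises(ep.ValidationError):
            ep.embed(raw, perplexity=10, seed=1)

    def test_sklearn_cross_check_separates_blobs(self, rng):
        """Independent route: sklearn's t-SNE on the same two-blob input also
        separates them, so the separation is a property of the method, not of
        this implementation."""
        from sklearn.manifold import TSNE

        from sklearn.neighbors import KNeighborsClassifier

        a = rng.normal(0.0, 0.3, size=(50, 11))
        b = rng.normal(0.0, 0.3, size=(50, 11)) + 8.0
        X = np.vstack([a, b])
        truth = np.repeat([0, 1], 50)
        Y = TSNE(n_components=3, perplexity=20, random_state=0,
                 method="exact").fit_transform(X)
        knn = KNeighborsClassifier(n_neighbors=5).fit(Y, truth)
        assert knn.score(Y, truth) >= 0.95


def test_joint_q_is_normalized(rng):
    Y = rng.normal(size=(20, 3))
    _, Q = _joint_q(Y)
    assert abs(Q.sum() - 1.0) < 1e-12
    assert np.all(np.diag(Q) == 0.0)
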