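"""k-means++ seeding, Lloyd iterations, EM mixtures, soft membership."""

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import vegseg as vs
from vegseg.clustering import (ClusterConfig, Standardization, _sq_dists,
                               kmeans_fit, kmeans_pp_seed, gmm_fit,
                               predict_soft, secondary_class, segment)


def brute_force_best_2partition(pts):
    """Exhaustive minimum inertia over all 2-partitions (oracle)."""
    n = len(pts)
    best = np.inf
    for bits in range(1, 2 ** n - 1):
        lab = np.array([(bits >> i) & 1 for i in range(n)])
        ss = 0.0
        for g in (0, 1):
            grp = pts[lab == g]
            ss += ((grp - grp.mean(axis=0)) ** 2).sum()
        best = min(best, ss)
    return best


class TestSeeding:
    def test_k1_returns_a_data_point(self, rng):
        pts = rng.normal(size=(20, 2))
        c = kmeans_pp_seed(pts, 1, np.random.default_rng(0))
        assert any(np.allclose(c[0], p) for p in pts)

    def test_two_separated_points_both_chosen(self):
        pts = np.array([[0.0], [1000.0]])
        for s in range(20):
            c = kmeans_pp_seed(pts, 2, np.random.default_rng(s))
            assert sorted(c.ravel()) == [0.0, 1000.0]

    def test_empirical_distribution_matches_d2_rule(self):
        """On a 3-point set the seeding distribution over (first, second)
        pairs is exactly computable; 10,000 draws agree within 3 sigma."""
        x = np.array([[0.0], [1.0], [5.0]])
        # analytic pair probabilities
        p_pair = {}
        for i in range(3):
            d2 = np.array([(x[j, 0] - x[i, 0]) ** 2 for j in range(3)])
            for j in range(3):
                if j != i:
                    p_pair[(i, j)] = (1 / 3) * d2[j] / d2.sum()
        n = 10_000
        rng = np.random.default_rng(42)
        counts = {k: 0 for k in p_pair}
        for _ in range(n):
            c = kmeans_pp_seed(x, 2, rng)
            i = int(np.flatnonzero(np.isclose(x.ravel(), c[0, 0]))[0])
            j = int(np.flatnonzero(np.isclose(x.ravel(), c[1, 0]))[0])
            counts[(i, j)] += 1
        for key, p in p_pair.items():
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(counts[key] / n - p) < 3 * sigma + 1e-9, key

    def test_k_exceeding_distinct_points(self):
        with pytest.raises(ValueError):
            kmeans_pp_seed(np.zeros((4, 2)), 2, np.random.default_rng(0))


class TestKMeans:
    def test_k1_closed_form(self, rng):
        pts = rng.normal(size=(40, 3))
        model, labels = kmeans_fit(pts, ClusterConfig(k=1, standardize=False))
        np.testing.assert_allclose(model.centroids[0], pts.mean(axis=0), atol=1e-12)
        expected = ((pts - pts.mean(axis=0)) ** 2).sum()
        assert model.inertia == pytest.approx(expected, rel=1e-12)

    def test_two_blob_perfect_recovery(self):
        g = np.random.default_rng(5)
        a = g.normal(size=(50, 2)) + [0, 0]
        b = g.normal(size=(50, 2)) + [20, 20]
        pts = np.vstack([a, b])
        truth = np.r_[np.zeros(50, int), np.ones(50, int)]
        _, labels = kmeans_fit(pts, ClusterConfig(k=2, seed=3, standardize=False))
        acc = max((labels == truth).mean(), (labels == 1 - truth).mean())
        assert acc == 1.0

    def test_small_instance_matches_exhaustive_optimum(self):
        pts = np.array([0.0, 0.2, 0.9, 4.0, 4.3, 5.1]).reshape(-1, 1)
        model, _ = kmeans_fit(pts, ClusterConfig(k=2, seed=0, standardize=False,
                                                 n_init=10))
        assert model.inertia == pytest.approx(brute_force_best_2partition(pts),
                                              rel=1e-10)

    def test_inertia_trace_non_increasing(self, rng):
        pts = rng.normal(size=(200, 4))
        model, _ = kmeans_fit(pts, ClusterConfig(k=3, seed=1, n_init=1))
        trace = np.array(model.inertia_trace)
        assert (np.diff(trace) <= 1e-9).all()
        assert model.inertia <= trace[0] + 1e-9

    def test_matches_sklearn_on_separated_blobs(self):
        from sklearn.cluster import KMeans
        g = np.random.default_rng(11)
        pts = np.vstack([g.normal(size=(40, 3)) + c
                         for c in ([0, 0, 0], [15, 0, 0], [0, 15, 0])])
        model, _ = kmeans_fit(pts, ClusterConfig(k=3, seed=2, standardize=False))
        sk = KMeans(n_clusters=3, n_init=10, random_state=0).fit(pts)
        assert model.inertia == pytest.approx(sk.inertia_, rel=1e-6)

    def test_standardization_changes_assignments_on_mixed_scales(self):
        """Two groups separated only in a small-scale channel; a large-scale
        nuisance channel dominates unstandardized distance."""
        g = np.random.default_rng(8)
        small = np.r_[np.zeros(30), np.ones(30) * 0.02]
        big = g.uniform(0, 255, 60)
        pts = np.c_[big, small]
        truth = np.r_[np.zeros(30, int), np.ones(30, int)]

        def acc(standardize):
            _, lab = kmeans_fit(pts, ClusterConfig(k=2, seed=4,
                                                   standardize=standardize))
            return max((lab == truth).mean(), (lab == 1 - truth).mean())

        assert acc(True) == 1.0
        assert acc(False) < 1.0

    def test_five_class_recovery(self, five_scene, five_stack, five_mask):
        segmap = vs.segment(five_stack, five_mask.keep, "kmeans",
                            ClusterConfig(seed=7))
        matched = vs.assign_classes(segmap, five_scene.truth_class)
        rep = vs.metrics(vs.confusion(matched, five_scene.truth_class, n_classes=5))
        assert rep.overall_accuracy >= 0.9


class TestGmm:
    def test_single_component_closed_form(self, rng):
        pts = rng.normal(size=(100, 2))
        model = gmm_fit(pts, ClusterConfig(k=1, standardize=False), reg_covar=1e-6)
        np.testing.assert_allclose(model.means[0], pts.mean(axis=0), atol=1e-8)
        expected = np.cov(pts, rowvar=False, bias=True) + 1e-6 * np.eye(2)
        np.testing.assert_allclose(model.covariances[0], expected, atol=1e-6)

    def test_1d_two_component_parameter_recovery(self):
        g = np.random.default_rng(123)
        pts = np.r_[g.normal(-3, 1, 1000), g.normal(3, 1, 1000)].reshape(-1, 1)
        model = gmm_fit(pts, ClusterConfig(k=2, seed=0, standardize=False,
                                           max_iter=50))
        means = np.sort(model.means.ravel())
        assert abs(means[0] - (-3)) < 0.2 and abs(means[1] - 3) < 0.2
        np.testing.assert_allclose(np.sort(model.weights), [0.5, 0.5], atol=0.05)

    def test_log_likelihood_non_decreasing(self, rng):
        pts = rng.normal(size=(300, 3))
        model = gmm_fit(pts, ClusterConfig(k=3, seed=2, standardize=False))
        trace = np.array(model.log_likelihood_trace)
        assert (np.diff(trace) >= -1e-6 * np.abs(trace[:-1])).all()

    def test_responsibilities_match_bayes_rule(self, rng):
        pts = rng.normal(size=(200, 2))
        model = gmm_fit(pts, ClusterConfig(k=3, seed=5, standardize=False))
        q = rng.normal(size=(10, 2))
        resp = predict_soft(model, q)
        dens = np.stack([model.weights[j] *
                         multivariate_normal(model.means[j],
                                             model.covariances[j]).pdf(q)
                         for j in range(3)], axis=1)
        np.testing.assert_allclose(resp, dens / dens.sum(axis=1, keepdims=True),
                                   atol=1e-10)

    def test_rows_sum_to_one(self, rng):
        pts = rng.normal(size=(150, 2))
        model = gmm_fit(pts, ClusterConfig(k=2, seed=1))
        resp = predict_soft(model, pts)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-6)

    def test_point_at_mean_of_separated_mixture(self):
        model = vs.GmmModel(
            weights=np.array([0.5, 0.5]),
            means=np.array([[0.0, 0.0], [50.0, 50.0]]),
            covariances=np.stack([np.eye(2)] * 2),
            log_likelihood_trace=[], converged=True,
            standardization=Standardization.identity(2))
        resp = predict_soft(model, np.array([[0.0, 0.0]]))
        assert resp[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_identical_components_give_uniform_membership(self):
        model = vs.GmmModel(
            weights=np.array([0.5, 0.5]),
            means=np.zeros((2, 2)),
            covariances=np.stack([np.eye(2)] * 2),
            log_likelihood_trace=[], converged=True,
            standardization=Standardization.identity(2))
        resp = predict_soft(model, np.array([[3.0, -1.0]]))
        np.testing.assert_allclose(resp[0], [0.5, 0.5], atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        model = gmm_fit(rng.normal(size=(50, 2)), ClusterConfig(k=2, seed=0))
        with pytest.raises(ValueError):
            predict_soft(model, rng.normal(size=(5, 3)))


class TestSecondaryClass:
    def test_forced_runner_up(self):
        resp = np.zeros((1, 3, 3))
        resp[0, 0] = [0.6, 0.3, 0.1]
        resp[0, 1] = [0.2, 0.7, 0.1]
        resp[0, 2] = [0.5, 0.1, 0.4]
        soft = vs.SoftMembership(responsibilities=resp,
                                 valid=np.ones((1, 3), dtype=bool))
        primary = vs.SegmentMap(labels=resp.argmax(axis=2))
        sec = secondary_class(soft, primary, 0)
        assert sec.labels[0, 0] == 1      # runner-up of (0.6, 0.3, 0.1)
        assert sec.labels[0, 2] == 2      # runner-up of (0.5, 0.1, 0.4)
        assert sec.labels[0, 1] == -1     # primary != given class

    def test_class_map_aggregates_components(self):
        # components 0 and 1 are both "class 0"; runner-up must be a class
        resp = np.array([[[0.45, 0.35, 0.20]]])
        soft = vs.SoftMembership(responsibilities=resp,
                                 valid=np.ones((1, 1), dtype=bool))
        primary = vs.SegmentMap(labels=np.array([[0]]))
        sec = secondary_class(soft, primary, 0, class_map={0: 0, 1: 0, 2: 1})
        assert sec.labels[0, 0] == 1

    def test_k1_rejected(self):
        soft = vs.SoftMembership(responsibilities=np.ones((1, 1, 1)),
                                 valid=np.ones((1, 1), dtype=bool))
        with pytest.raises(ValueError):
            secondary_class(soft, vs.SegmentMap(labels=np.zeros((1, 1), int)), 0)


class TestSegment:
    def test_kmeans_produces_k_labels(self, five_stack, five_mask):
        segmap = segment(five_stack, five_mask.keep, "kmeans",
                         ClusterConfig(seed=7))
        assert segmap.unique_labels().size == 5
        assert (segmap.labels[~five_mask.keep] == -1).all()

    def test_gmm_soft_membership_normalized(self, five_stack, five_mask):
        _, soft = segment(five_stack, five_mask.keep, "gmm",
                          ClusterConfig(seed=7))
        sums = soft.responsibilities[soft.valid].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_deterministic_for_fixed_seed(self, five_stack, five_mask):
        a = segment(five_stack, five_mask.keep, "kmeans", ClusterConfig(seed=9))
        b = segment(five_stack, five_mask.keep, "kmeans", ClusterConfig(seed=9))
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_empty_pervious_set_rejected(self, five_stack):
        keep = np.zeros(five_stack.nodata_mask.shape, dtype=bool)
        with pytest.raises(ValueError):
            segment(five_stack, keep, "kmeans", ClusterConfig())
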