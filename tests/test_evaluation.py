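"""Davies-Bouldin, confusion metrics, channel importance, class matching."""

import numpy as np
import pytest

import vegseg as vs
from vegseg.evaluation import (BENCHMARK_CLASS_ORDER, BENCHMARK_CONFUSION,
                               ConfusionMatrix, assign_classes, confusion,
                               davies_bouldin, gini_importance, majority_mapping,
                               match_labels, metrics)


def dbi_bruteforce(X, labels):
    """Independent literal evaluation of the Davies-Bouldin formula."""
    uniq = sorted(set(labels.tolist()))
    cents = {u: X[labels == u].mean(axis=0) for u in uniq}
    s = {u: np.mean([np.linalg.norm(x - cents[u]) for x in X[labels == u]])
         for u in uniq}
    total = 0.0
    for i in uniq:
        worst = 0.0
        for j in uniq:
            if i == j:
                continue
            d = np.linalg.norm(cents[i] - cents[j])
            worst = max(worst, (s[i] + s[j]) / d)
        total += worst
    return total / len(uniq)


class TestDaviesBouldin:
    def test_two_tight_singletons(self):
        X = np.array([[0.0], [100.0]])
        assert davies_bouldin(X, np.array([0, 1])) == 0.0

    def test_hand_computed_toy(self):
        X = np.array([0.0, 1.0, 10.0, 11.0]).reshape(-1, 1)
        labels = np.array([0, 0, 1, 1])
        # spreads 0.5 each, centroid distance 10 -> (0.5+0.5)/10 = 0.1
        assert davies_bouldin(X, labels) == pytest.approx(0.1, abs=1e-12)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(20):
            k = rng.integers(2, 5)
            X = rng.normal(size=(50, 3))
            labels = rng.integers(0, k, size=50)
            if np.unique(labels).size < 2:
                continue
            assert davies_bouldin(X, labels) == pytest.approx(
                dbi_bruteforce(X, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import davies_bouldin_score
        X = rng.normal(size=(80, 4))
        labels = rng.integers(0, 3, size=80)
        assert davies_bouldin(X, labels) == pytest.approx(
            davies_bouldin_score(X, labels), abs=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            davies_bouldin(np.zeros((5, 2)), np.zeros(5, int))

    def test_coincident_centroids_named(self):
        X = np.array([[0.0], [0.0], [0.0], [0.0]])
        with pytest.raises(ValueError, match="coincident"):
            davies_bouldin(X, np.array([0, 0, 1, 1]))


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        truth = np.array([[0, 1], [2, 2]])
        cm = confusion(truth, truth, n_classes=3)
        np.testing.assert_array_equal(cm.counts, np.diag([1, 1, 2]))

    def test_sentinels_excluded(self):
        pred = np.array([[0, -1], [1, 1]])
        truth = np.array([[0, 1], [-1, 1]])
        cm = confusion(pred, truth, n_classes=2)
        assert cm.total == 2

    def test_benchmark_matrices_share_one_pixel_total(self):
        totals = {e: int(M.sum()) for e, M in BENCHMARK_CONFUSION.items()}
        assert len(set(totals.values())) == 1

    def test_three_tiles_contain_1920000_pixels(self):
        grid = vs.tile(vs.Raster(values=np.zeros((2400, 800, 1), dtype=np.uint8),
                                 channel_names=("b",)), 800, 800)
        assert len(grid) == 3
        assert sum(t.raster.height * t.raster.width for t in grid) == 1_920_000

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.full((2, 2), -1), np.zeros((2, 2), int))


class TestMetrics:
    def test_identity_matrix_gives_all_ones(self):
        rep = metrics(ConfusionMatrix(counts=np.eye(3, dtype=int) * 7,
                                      class_names=("a", "b", "c")))
        assert rep.overall_accuracy == 1.0
        assert all(v == 1.0 for v in rep.recall.values())
        assert all(v == 1.0 for v in rep.f1.values())

    @pytest.mark.parametrize("engine,which,cls,expected", [
        ("kmeans", "overall", None, 0.80),
        ("kmeans", "f1", "ground/soil", 0.73),
        ("kmeans", "precision", "grass", 0.81),
        ("kmeans", "f1", "trees/shrubs", 0.78),
        ("gmm", "precision", "trees/shrubs", 0.35),
        ("gmm", "f1", "water/shadow", 0.75),
        ("cnn", "recall", "trees/shrubs", 0.88),
    ])
    def test_benchmark_metric_reconstruction(self, engine, which, cls, expected):
        """Per-class metrics recomputed from the published confusion
        matrices agree with the published two-decimal values."""
        cm = ConfusionMatrix(counts=BENCHMARK_CONFUSION[engine],
                             class_names=BENCHMARK_CLASS_ORDER)
        rep = metrics(cm)
        value = rep.overall_accuracy if which == "overall" else getattr(rep, which)[cls]
        assert round(value, 2) == pytest.approx(expected)
        # robust to truncation as well as rounding
        assert np.floor(value * 100) / 100 == pytest.approx(expected, abs=0.011)

    def test_zero_denominator_flagged(self):
        counts = np.array([[3, 0], [0, 0]])
        rep = metrics(ConfusionMatrix(counts=counts, class_names=("a", "b")))
        assert rep.precision["b"] == 0.0
        assert "b" in rep.zero_denominator_classes

    def test_f1_is_harmonic_mean(self):
        cm = ConfusionMatrix(counts=BENCHMARK_CONFUSION["kmeans"],
                             class_names=BENCHMARK_CLASS_ORDER)
        rep = metrics(cm)
        for c in BENCHMARK_CLASS_ORDER:
            p, r = rep.precision[c], rep.recall[c]
            assert rep.f1[c] == pytest.approx(2 * p * r / (p + r), rel=1e-12)


class TestGiniImportance:
    def test_single_driver_channel_dominates(self, rng):
        """Labels thresholded on one channel of an independent-channel
        stack concentrate nearly all the importance on that channel."""
        from vegseg.indices import ChannelStack, IndexParams
        vals = rng.uniform(size=(60, 60, 10))
        raster = vs.Raster(values=vals, channel_names=vs.STACK_CHANNELS)
        stack = ChannelStack(raster=raster, index_params=IndexParams())
        labels = (vals[:, :, 1] > 0.5).astype(np.int64)  # green only
        rep = gini_importance(stack, labels, seed=0)
        assert rep.coefficients["green"] > 0.9
        assert rep.ranking[0] == "green"

    def test_nir_ranks_first_when_classes_are_nir_separated(self):
        """Vegetation covers that differ only in near-infrared reflectance
        put NIR at the top of the importance ranking."""
        from vegseg.synthetic_data import (Primitive, SceneSpec,
                                           SignatureTable, generate_scene)
        means = {
            "grass": np.array([0.15, 0.25, 0.18, 0.30]),
            "tree": np.array([0.15, 0.25, 0.18, 0.60]),
            "soil": np.array([0.15, 0.25, 0.18, 0.45]),
        }
        sig = SignatureTable(means=means,
                             covs={m: (0.012 ** 2) * np.eye(4) for m in means})
        spec = SceneSpec(height=128, width=128, background="grass", seed=0,
                         primitives=[
                             Primitive("rectangle", "soil", (0.0, 0.5, 1.0, 1.0)),
                             Primitive("ellipse", "tree", (0.5, 0.25, 0.2, 0.18))],
                         boundary_mix_width=0, signatures=sig)
        scene = generate_scene(spec)
        stack = vs.build_stack(vs.scale_dn(scene.raster))
        rep = gini_importance(stack, scene.truth_class, seed=2)
        assert rep.ranking[0] == "nir"

    def test_coefficients_sum_to_one(self, five_stack):
        labels = (five_stack.channel("ndvi") > 0.45).astype(np.int64)
        rep = gini_importance(five_stack, labels, seed=1)
        assert sum(rep.coefficients.values()) == pytest.approx(1.0, abs=1e-6)

    def test_single_class_rejected(self, five_stack):
        with pytest.raises(ValueError):
            gini_importance(five_stack,
                            np.zeros(five_stack.nodata_mask.shape, np.int64), 0)


class TestAssignClasses:
    def test_permuted_identity_recovered(self, rng):
        truth = rng.integers(0, 4, size=(30, 30))
        perm = np.array([2, 3, 0, 1])
        pred = perm[truth]
        matched = assign_classes(vs.SegmentMap(labels=pred), truth,
                                 class_names=tuple("abcd"))
        np.testing.assert_array_equal(matched.labels, truth)

    def test_majority_overlap(self):
        truth = np.array([1] * 19 + [0]).reshape(4, 5)
        pred = np.zeros((4, 5), dtype=np.int64)
        mapping = match_labels(pred, truth)
        assert mapping[0] == 1

    def test_explicit_mapping_merges(self):
        segmap = vs.SegmentMap(labels=np.array([[0, 1], [2, 2]]))
        out = assign_classes(segmap, {0: 1, 1: 1, 2: 0})
        np.testing.assert_array_equal(out.labels, [[1, 1], [0, 0]])

    def test_uncovered_label_rejected(self):
        segmap = vs.SegmentMap(labels=np.array([[0, 1]]))
        with pytest.raises(ValueError):
            assign_classes(segmap, {0: 1})

    def test_matching_is_optimal(self, five_scene, five_stack, five_mask):
        segmap = vs.segment(five_stack, five_mask.keep, "kmeans",
                            vs.ClusterConfig(seed=7))
        matched = assign_classes(segmap, five_scene.truth_class)
        truth = five_scene.truth_class
        sel = matched.valid & (truth >= 0)
        acc_matched = (matched.labels[sel] == truth[sel]).mean()
        acc_raw = (segmap.labels[sel] == truth[sel]).mean()
        assert acc_matched >= acc_raw

    def test_marginals_invariant_under_matching(self, five_scene, five_stack,
                                                five_mask):
        segmap = vs.segment(five_stack, five_mask.keep, "kmeans",
                            vs.ClusterConfig(seed=7))
        matched = assign_classes(segmap, five_scene.truth_class)
        cm_raw = confusion(segmap, five_scene.truth_class, n_classes=5)
        cm_matched = confusion(matched, five_scene.truth_class, n_classes=5)
        np.testing.assert_array_equal(np.sort(cm_raw.counts.sum(axis=1)),
                                      np.sort(cm_matched.counts.sum(axis=1)))
        np.testing.assert_array_equal(cm_raw.counts.sum(axis=0),
                                      cm_matched.counts.sum(axis=0))

    def test_majority_mapping_merges_split_segments(self):
        truth = np.array([[0, 0, 1, 1]])
        pred = np.array([[0, 1, 2, 2]])
        assert majority_mapping(pred, truth) == {0: 0, 1: 0, 2: 1}
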