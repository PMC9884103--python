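"""Metrics, ROC/AUC, DeLong, chi-square, binary restriction, rendered maps."""

import numpy as np
import pytest
import scipy.stats
from sklearn.metrics import roc_auc_score

from msiaudit.classifier import PredictionBatch
from msiaudit.evaluation import (
    binarize_two_class,
    chi_square_2x2,
    confusion_and_metrics,
    delong_auc_test,
    pairwise_auc,
    render_maps,
    roc_one_vs_rest,
)


def batch(probs, labels, names=None, **kw):
    probs = np.asarray(probs, dtype=float)
    if names is None:
        names = tuple(f"c{i}" for i in range(probs.shape[1]))
    return PredictionBatch(probs=probs, labels=np.asarray(labels), class_names=names,
                           **kw)


def random_batch(rng, n=40, k=3):
    p = rng.dirichlet(np.ones(k), size=n)
    return batch(p, rng.integers(0, k, size=n))


class TestConfusionAndMetrics:
    def test_all_correct_identity_pattern(self):
        b = batch([[0.9, 0.1], [0.1, 0.9], [0.8, 0.2]], [0, 1, 0])
        cm, m = confusion_and_metrics(b)
        assert np.trace(cm.counts) == 3
        assert m.micro_accuracy == 1.0 and m.macro_accuracy == 1.0
        pct = cm.percentages()
        np.testing.assert_allclose(np.diag(pct), 100.0)

    def test_hand_built_three_class_batch(self):
        # 6 patches; predictions by argmax: [0, 1, 1, 2, 0, 0]
        probs = [[0.8, 0.1, 0.1], [0.2, 0.7, 0.1], [0.1, 0.8, 0.1],
                 [0.2, 0.2, 0.6], [0.9, 0.05, 0.05], [0.5, 0.3, 0.2]]
        labels = [0, 1, 0, 2, 1, 0]
        cm, m = confusion_and_metrics(batch(probs, labels))
        expected = np.array([[2, 1, 0], [1, 1, 0], [0, 0, 1]])
        np.testing.assert_array_equal(cm.counts, expected)
        assert m.micro_accuracy == pytest.approx(4 / 6)
        assert m.macro_accuracy == pytest.approx((2 / 3 + 1 / 2 + 1) / 3)

    def test_percentage_rows_sum_to_100(self, rng):
        b = random_batch(rng, n=200, k=5)
        cm, _ = confusion_and_metrics(b)
        pct = cm.percentages()
        rows = ~np.isnan(pct).all(axis=1)
        np.testing.assert_allclose(pct[rows].sum(axis=1), 100.0, atol=0.01)

    def test_micro_equals_patch_level_proportion(self, rng):
        b = random_batch(rng, n=500, k=4)
        cm, m = confusion_and_metrics(b)
        direct = float(np.mean(b.predicted == b.labels))
        assert abs(m.micro_accuracy - direct) < 1e-12
        assert abs(cm.micro_accuracy() - direct) < 1e-12

    def test_label_out_of_range_rejected(self):
        b = batch([[0.5, 0.5]], [0])
        b.labels = np.array([5])
        with pytest.raises(ValueError):
            confusion_and_metrics(b)


class TestRoc:
    def test_perfect_separation_auc_one(self):
        b = batch([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]], [0, 0, 1, 1])
        *_, auc = roc_one_vs_rest(b, 1)
        assert auc == 1.0

    def test_identical_scores_auc_half(self):
        b = batch([[0.5, 0.5]] * 6, [0, 1, 0, 1, 0, 1])
        *_, auc = roc_one_vs_rest(b, 1)
        assert auc == 0.5

    def test_enumerated_four_pair_example(self):
        # scores [0.9, 0.8, 0.4, 0.3], labels [1, 0, 1, 0] -> 3 of 4 pairs
        # concordant -> AUC 0.75
        probs = np.array([[0.1, 0.9], [0.2, 0.8], [0.6, 0.4], [0.7, 0.3]])
        b = batch(probs, [1, 0, 1, 0])
        *_, auc = roc_one_vs_rest(b, 1)
        assert auc == pytest.approx(0.75, abs=1e-12)

    def test_matches_sklearn_on_random_instances(self, rng):
        for _ in range(50):
            scores = np.round(rng.random(30), 2)  # ties likely
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                continue
            assert pairwise_auc(scores, labels == 1) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_flagged_nan(self):
        b = batch([[0.5, 0.5]] * 3, [0, 0, 0])
        *_, auc = roc_one_vs_rest(b, 1)
        assert np.isnan(auc)

    def test_curve_monotone_and_anchored(self, rng):
        b = random_batch(rng, n=100, k=2)
        fpr, tpr, thr, _ = roc_one_vs_rest(b, 0)
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


class TestDeLong:
    def test_identical_scores_z_zero_p_one(self, rng):
        s = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        r = delong_auc_test(s, s, labels)
        assert r.z == 0.0 and r.p_value == 1.0

    def test_auc_equals_pairwise_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() < 2 or (1 - labels).sum() < 2:
                continue
            r = delong_auc_test(scores, rng.random(n), labels)
            assert r.auc_a == pytest.approx(pairwise_auc(scores, labels == 1),
                                            abs=1e-12)

    def test_variance_close_to_bootstrap(self, rng):
        n = 200
        labels = rng.integers(0, 2, size=n)
        scores = rng.normal(size=n) + 0.8 * labels
        r = delong_auc_test(scores, rng.normal(size=n), labels)
        boot = []
        for _ in range(2000):
            idx = rng.integers(0, n, size=n)
            if labels[idx].sum() < 2 or (1 - labels[idx]).sum() < 2:
                continue
            boot.append(pairwise_auc(scores[idx], labels[idx] == 1))
        boot_var = np.var(boot)
        assert r.var_a == pytest.approx(boot_var, rel=0.10)

    def test_clearly_different_scores_significant(self, rng):
        n = 400
        labels = rng.integers(0, 2, size=n)
        good = labels + 0.1 * rng.normal(size=n)
        noise = rng.normal(size=n)
        r = delong_auc_test(good, noise, labels)
        assert r.p_value < 0.001 and r.significant

    def test_too_few_examples_rejected(self):
        with pytest.raises(ValueError):
            delong_auc_test([0.1, 0.2, 0.3], [0.3, 0.2, 0.1], [1, 0, 0])


class TestChiSquare:
    def test_identical_proportions_statistic_zero(self):
        stat, p = chi_square_2x2(50, 50, 50, 50)
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_128(self):
        stat, _ = chi_square_2x2(10, 90, 90, 10)
        assert stat == pytest.approx(128.0, abs=1e-12)

    def test_symmetric_under_group_swap(self):
        a = chi_square_2x2(30, 70, 55, 45)
        b = chi_square_2x2(55, 45, 30, 70)
        assert a == pytest.approx(b)

    def test_matches_scipy_without_correction(self, rng):
        for _ in range(20):
            t = rng.integers(1, 100, size=4)
            stat, p = chi_square_2x2(*t)
            ref = scipy.stats.chi2_contingency(t.reshape(2, 2), correction=False)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 10, 10)


class TestBinarize:
    def test_equal_probabilities_give_half(self):
        b = batch([[0.2, 0.2, 0.6]], [0])
        r = binarize_two_class(b, 0, 1)
        assert r.preds.probs[0, 0] == pytest.approx(0.5)

    def test_renormalization_example(self):
        probs = np.zeros((1, 11))
        probs[0, 2] = 0.3
        probs[0, 5] = 0.1
        probs[0, 0] = 0.6
        b = batch(probs, [2])
        r = binarize_two_class(b, 2, 5)
        assert r.preds.probs[0, 0] == pytest.approx(0.75)  # 0.3 / 0.4

    def test_pairs_sum_to_one(self, rng):
        b = random_batch(rng, n=100, k=4)
        r = binarize_two_class(b, 1, 3)
        np.testing.assert_allclose(r.preds.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_restriction_not_worse_than_multiclass(self, rng):
        # removing competing classes can only help a calibrated classifier
        b = random_batch(rng, n=400, k=5)
        mask = (b.labels == 0) | (b.labels == 1)
        multi_acc = float(np.mean(b.predicted[mask] == b.labels[mask]))
        r = binarize_two_class(b, 0, 1)
        bin_acc = r.preds.micro_accuracy()
        assert bin_acc >= multi_acc - 1e-12

    def test_zero_sum_patches_excluded_with_count(self):
        probs = np.array([[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.6, 0.4]])
        b = batch(probs, [2, 2])
        r = binarize_two_class(b, 2, 3)
        assert r.n_excluded == 1
        assert r.preds.labels.size == 1

    def test_same_class_pair_rejected(self, rng):
        with pytest.raises(ValueError):
            binarize_two_class(random_batch(rng), 1, 1)


class TestRenderMaps:
    @staticmethod
    def _scene_preds():
        # true labels all class 0: correct-class probabilities are 1.0, 0.0, 0.6
        probs = np.array([[1.0, 0.0], [0.0, 1.0], [0.6, 0.4]])
        coords = np.array([[0, 0], [0, 1], [1, 1]])
        return batch(probs, [0, 0, 0], names=("a", "b"), coords=coords)

    def test_label_map_uses_class_colors_on_foreground_tiles(self):
        preds = self._scene_preds()
        m = render_maps((64, 64), preds, mode="label_map")
        # background tile (1, 0) stays gray
        np.testing.assert_allclose(m.canvas[32:, :32], 0.5)
        # predicted tile colors match the legend
        np.testing.assert_allclose(m.canvas[0, 0], m.legend["a"])
        np.testing.assert_allclose(m.canvas[0, 40], m.legend["b"])

    def test_probability_endpoints_map_to_scale_ends(self):
        from matplotlib import colormaps

        preds = self._scene_preds()
        m = render_maps((64, 64), preds, mode="probability_heatmap")
        cmap = colormaps["viridis"]
        np.testing.assert_allclose(m.canvas[0, 0], cmap(1.0)[:3])  # p_correct = 1
        np.testing.assert_allclose(m.canvas[0, 40], cmap(0.0)[:3])  # p_correct = 0

    def test_tile_placement_round_trips_with_tiler(self):
        from test_patchwork import make_scene
        from msiaudit.patchwork import tile_foreground_patches

        mask = np.ones((64, 64), dtype=bool)
        mask[0, 0] = False
        rec = make_scene(64, 64, mask=mask)
        _, coords = tile_foreground_patches(rec.cube, rec.mask)
        probs = np.tile([1.0, 0.0], (coords.shape[0], 1))
        preds = batch(probs, np.zeros(coords.shape[0], int), names=("a", "b"),
                      coords=coords)
        m = render_maps((64, 64), preds, mode="label_map")
        np.testing.assert_allclose(m.canvas[:32, :32], 0.5)  # dropped tile gray
        np.testing.assert_allclose(m.canvas[40, 40], m.legend["a"])

    def test_out_of_range_coordinate_rejected(self):
        preds = batch(np.array([[1.0, 0.0]]), [0], names=("a", "b"),
                      coords=np.array([[5, 0]]))
        with pytest.raises(ValueError):
            render_maps((64, 64), preds, mode="label_map")

    def test_save_png(self, tmp_path):
        m = render_maps((64, 64), self._scene_preds(), mode="label_map")
        p = tmp_path / "map.png"
        m.save(p)
        assert p.exists() and p.stat().st_size > 0
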