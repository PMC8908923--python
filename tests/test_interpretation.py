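"""CAM computation, upper-quartile thresholding, part-overlap quantification
and the ANOVA + Tukey HSD statistics."""

import numpy as np
import pytest
from scipy.stats import f_oneway
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from wormsight.classification import WormNetClassifier
from wormsight.dataio import PartMaskSet
from wormsight.interpretation import (
    SaliencyMap,
    anova_tukey,
    compute_cam,
    interpret_cohort,
    overlap_fractions,
    threshold_upper_quartile,
)
from wormsight.nn import WormNetModel


class FakeGapModel:
    """Hand-settable final feature maps and class weights."""

    def __init__(self, feats, weights, input_size=None):
        self._feats = np.asarray(feats, dtype=np.float32)  # (g, g, K)
        self.cam_weights = np.asarray(weights, dtype=np.float32)  # (K, 2)
        self.input_size = input_size or self._feats.shape[0]

    def forward(self, x, train=False):
        self.feature_maps_ = self._feats[None]
        return np.array([[0.5, 0.5]])


class TestComputeCam:
    def test_single_filter_linearity(self):
        f = np.arange(9, dtype=float).reshape(3, 3, 1)
        model = FakeGapModel(f, [[2.0, 0.0]])
        cam = compute_cam(model, np.zeros((3, 3)), class_index=0)
        np.testing.assert_allclose(cam.values, 2.0 * f[..., 0], atol=1e-6)

    def test_zero_weights_give_zero_map(self):
        f = np.random.default_rng(0).random((3, 3, 4))
        model = FakeGapModel(f, np.zeros((4, 2)))
        cam = compute_cam(model, np.zeros((3, 3)), class_index=1)
        assert (cam.values == 0).all()

    def test_two_filter_weighted_sum_matches_hand_computation(self):
        f1 = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 0.0], [3.0, 0.0, 1.0]])
        f2 = np.array([[0.0, 1.0, 0.0], [2.0, 0.0, 1.0], [0.0, 2.0, 0.0]])
        w = np.array([[0.5, -1.0], [2.0, 3.0]])
        model = FakeGapModel(np.stack([f1, f2], axis=-1), w)
        cam0 = compute_cam(model, np.zeros((3, 3)), 0)
        np.testing.assert_allclose(cam0.values, 0.5 * f1 + 2.0 * f2, atol=1e-6)
        cam1 = compute_cam(model, np.zeros((3, 3)), 1)
        np.testing.assert_allclose(cam1.values, -1.0 * f1 + 3.0 * f2, atol=1e-6)

    def test_additivity_over_filters(self):
        rng = np.random.default_rng(1)
        f = rng.random((3, 3, 2))
        w = rng.random((2, 2))
        total = compute_cam(FakeGapModel(f, w), np.zeros((3, 3)), 0).values
        parts = sum(
            compute_cam(FakeGapModel(f[..., [k]], w[[k]]), np.zeros((3, 3)), 0).values
            for k in range(2))
        np.testing.assert_allclose(total, parts, atol=1e-6)

    def test_upsampling_to_input_resolution(self):
        f = np.random.default_rng(2).random((3, 3, 1))
        model = FakeGapModel(f, [[1.0, 0.0]], input_size=96)
        cam = compute_cam(model, np.zeros((96, 96)), 0)
        assert cam.values.shape == (96, 96)

    def test_flatten_head_rejected(self):
        m = WormNetModel(input_size=32, filters=(2, 2, 2, 2, 2),
                         head_mode="flatten_fc", seed=0)
        with pytest.raises(ValueError, match="gap_cam"):
            compute_cam(m, np.zeros((32, 32)), 0)


class TestUpperQuartile:
    def test_four_pixel_hand_example(self):
        sal = SaliencyMap(np.array([[0.0, 1.0], [2.0, 3.0]]), class_index=0)
        out = threshold_upper_quartile(sal)
        # Q3 of {0,1,2,3} with linear interpolation is 2.25: only the 3 stays
        assert out.tolist() == [[False, False], [False, True]]

    def test_constant_map_warns_and_marks_all(self):
        sal = SaliencyMap(np.full((4, 4), 1.5), class_index=0)
        with pytest.warns(UserWarning, match="constant"):
            out = threshold_upper_quartile(sal)
        assert out.all()

    def test_uniform_map_marks_a_quarter(self):
        rng = np.random.default_rng(3)
        values = rng.random((200, 200))
        frac = threshold_upper_quartile(SaliencyMap(values, 0)).mean()
        assert abs(frac - 0.25) < 0.02

    def test_ties_at_threshold_kept(self):
        values = np.array([[1.0, 1.0], [1.0, 2.0]])
        out = threshold_upper_quartile(SaliencyMap(values, 0))
        # Q3 = 1.75 -> only the 2; but with >= a tie AT Q3 would be kept
        assert out.sum() == 1
        tied = np.array([0.0, 2.0, 2.0, 2.0]).reshape(2, 2)
        assert threshold_upper_quartile(SaliencyMap(tied, 0)).sum() == 3


def square_masks(size=8):
    anterior = np.zeros((size, size), bool)
    mid = np.zeros((size, size), bool)
    posterior = np.zeros((size, size), bool)
    anterior[0:2, 0:4] = True
    mid[3:5, 0:4] = True
    posterior[6:8, 0:4] = True
    whole = anterior | mid | posterior
    return PartMaskSet(anterior=anterior, mid=mid, posterior=posterior, whole=whole)


class TestOverlapFractions:
    def test_counting_example(self):
        parts = square_masks()
        salient = np.zeros((8, 8), bool)
        salient[0, 0] = True          # anterior
        salient[3, 0] = True          # mid
        salient[6, 0] = salient[7, 0] = True  # posterior x2
        salient[0, 7] = True          # outside the worm
        rec = overlap_fractions(salient, parts)
        assert (rec.pct_anterior, rec.pct_mid, rec.pct_posterior) == (25, 25, 50)
        assert not rec.flagged
        assert rec.total() == pytest.approx(100.0, abs=1e-6)

    def test_salient_outside_worm_is_flagged(self):
        parts = square_masks()
        salient = np.zeros((8, 8), bool)
        salient[0, 6] = True
        rec = overlap_fractions(salient, parts)
        assert rec.flagged and rec.total() == 0.0

    def test_percentages_conserve_under_random_masks(self):
        rng = np.random.default_rng(5)
        parts = square_masks()
        for _ in range(20):
            salient = rng.random((8, 8)) > 0.5
            rec = overlap_fractions(salient, parts)
            if not rec.flagged:
                assert rec.total() == pytest.approx(100.0, abs=1e-6)

    def test_contested_pixel_goes_to_highest_probability_part(self):
        size = 4
        a = np.zeros((size, size), bool)
        m = np.zeros((size, size), bool)
        p = np.zeros((size, size), bool)
        a[0, 0] = m[0, 0] = True  # contested pixel
        probs = np.zeros((size, size, 3), np.float32)
        probs[0, 0] = [0.6, 0.9, 0.0]  # mid wins
        parts = PartMaskSet(anterior=a, mid=m, posterior=p, whole=a | m | p)
        salient = np.ones((size, size), bool)
        rec = overlap_fractions(salient, parts, part_probs=probs)
        assert rec.pct_mid == 100.0
        # without probabilities the tie resolves toward the more anterior part
        rec2 = overlap_fractions(salient, parts)
        assert rec2.pct_anterior == 100.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            overlap_fractions(np.ones((4, 4), bool), square_masks(8))


class TestAnovaTukey:
    def test_identical_groups_give_zero_f(self):
        res = anova_tukey({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.F == 0.0 and res.p == 1.0
        assert len(res.tukey) == 3
        assert all(t["p_adj"] > 0.99 for t in res.tukey)

    def test_single_outlying_group_detected(self):
        rng = np.random.default_rng(0)
        jitter = 1e-3 * rng.standard_normal((3, 4))
        res = anova_tukey({"g1": jitter[0], "g2": jitter[1],
                           "g3": 10.0 + jitter[2]})
        assert res.p < 1e-6
        flagged = {frozenset(t["pair"]) for t in res.tukey if t["p_adj"] < 0.01}
        assert flagged == {frozenset({"g1", "g3"}), frozenset({"g2", "g3"})}

    def test_matches_reference_implementations(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            groups = {c: rng.normal(rng.uniform(-1, 1), 1.0,
                                    size=int(rng.integers(5, 25)))
                      for c in "abc"}
            res = anova_tukey(groups)
            F, p = f_oneway(*groups.values())
            assert res.F == pytest.approx(F, abs=1e-6)
            assert res.p == pytest.approx(p, abs=1e-6)
            values = np.concatenate(list(groups.values()))
            labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
            ref = pairwise_tukeyhsd(values, labels)
            np.testing.assert_allclose([t["p_adj"] for t in res.tukey],
                                       ref.pvalues, atol=1e-6)
            np.testing.assert_allclose([t["mean_diff"] for t in res.tukey],
                                       ref.meandiffs, atol=1e-9)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="2 observations"):
            anova_tukey({"a": [1.0], "b": [1, 2], "c": [1, 2]})

    def test_accepts_overlap_records(self):
        from wormsight.interpretation import OverlapRecord

        records = [OverlapRecord(f"w{i}", 0, 30.0 + i, 35.0, 35.0 - i)
                   for i in range(6)]
        res = anova_tukey(records)
        assert set(res.group_means) == {"anterior", "mid", "posterior"}


class TestInterpretCohort:
    def _zero_cam_classifier(self):
        clf = WormNetClassifier(input_size=96, filters=(2, 2, 2, 2, 4),
                                head_mode="gap_cam", seed=0)
        clf.classes_ = np.array([0, 1])
        clf.model_ = clf._build()
        clf.model_.class_dense.W[...] = 0.0
        clf.model_.class_dense.b[...] = 0.0
        return clf

    def test_constant_cams_recover_part_area_fractions(self, small_cohort):
        clf = self._zero_cam_classifier()
        worms = small_cohort.worms[:4]
        images = np.stack([w.image for w in worms])
        labels = np.zeros(len(worms), dtype=int)
        table, stats, n_flagged = interpret_cohort(
            clf, None, images, labels,
            mask_sets=[w.masks for w in worms])
        assert n_flagged == 0
        assert len(table) == len(worms)
        for row, w in zip(table.itertuples(), worms):
            areas = np.array([w.masks.anterior.sum(), w.masks.mid.sum(),
                              w.masks.posterior.sum()], dtype=float)
            expected = 100.0 * areas / areas.sum()
            np.testing.assert_allclose(
                [row.pct_anterior, row.pct_mid, row.pct_posterior],
                expected, atol=1e-6)

    def test_requires_masks_or_segmenter(self):
        clf = self._zero_cam_classifier()
        with pytest.raises(ValueError, match="segmenter"):
            interpret_cohort(clf, None, np.zeros((1, 96, 96)), np.zeros(1))
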