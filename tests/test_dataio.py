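"""Loading, class labels, splits, augmentation and ablation transforms."""

import dataclasses

import imageio.v3 as iio
import numpy as np
import pytest

from wormsight.dataio import (
    AugmentationConfig,
    PartMaskSet,
    WormImage,
    ablate_worm,
    assign_lifespan_class,
    assign_movement_class,
    augment_stream,
    crop_center,
    load_image,
    mask_background,
    normalize_minmax,
    read_dataset_dir,
    split_by_worm_id,
    write_mask_set,
    read_mask_set,
)
from wormsight.synthetic import WormRecord


def record(worm_id="w0", lifespan=10.0, distance=100.0):
    return WormRecord(worm_id=worm_id, adult_day=1, lifespan_days=lifespan,
                      total_distance=distance)


class TestLoadImage:
    def test_resamples_to_target_size(self, tmp_path):
        rng = np.random.default_rng(0)
        path = tmp_path / "big.png"
        iio.imwrite(path, rng.integers(0, 255, (300, 300), dtype=np.uint8))
        img = load_image(path, target_size=96)
        assert img.pixels.shape == (96, 96)
        assert 0.0 <= img.pixels.min() and img.pixels.max() <= 1.0
        assert img.pixel_size == pytest.approx(580.5 / 96)

    def test_constant_image_is_rejected(self, tmp_path):
        path = tmp_path / "flat.png"
        iio.imwrite(path, np.full((32, 32), 7, dtype=np.uint8))
        with pytest.raises(ValueError, match="dynamic range"):
            load_image(path)

    def test_minmax_normalization_of_ramp(self):
        ramp = np.arange(16, dtype=float).reshape(4, 4)
        out = normalize_minmax(ramp)
        assert out.min() == 0.0 and out.max() == 1.0
        np.testing.assert_allclose(out, ramp / 15.0, atol=1e-7)
        assert (np.diff(out, axis=1) > 0).all()


class TestCropCenter:
    def test_900_to_800_crop_offsets(self):
        pixels = np.zeros((900, 900), dtype=np.float32)
        pixels[50, 50] = 1.0  # first retained pixel
        out = crop_center(WormImage(pixels), 800)
        assert out.pixels.shape == (800, 800)
        assert out.pixels[0, 0] == 1.0

    def test_full_size_crop_is_identity(self):
        img = WormImage(np.random.default_rng(0).random((32, 32)))
        out = crop_center(img, 32)
        assert np.array_equal(out.pixels, img.pixels)

    def test_small_example_indices(self):
        pixels = np.arange(25, dtype=float).reshape(5, 5) / 24
        out = crop_center(WormImage(pixels), 3)
        np.testing.assert_allclose(out.pixels, pixels[1:4, 1:4], atol=1e-7)

    def test_oversized_crop_rejected(self):
        with pytest.raises(ValueError):
            crop_center(WormImage(np.zeros((10, 10)) + 0.5), 11)


class TestClassAssignment:
    @pytest.mark.parametrize("lifespan,expected",
                             [(7.0, "short"), (8.0, "long"), (7.6, "short"),
                              (0.0, "short"), (14.0, "long")])
    def test_lifespan_threshold(self, lifespan, expected):
        assert assign_lifespan_class(record(lifespan=lifespan)) == expected

    def test_missing_lifespan_raises(self):
        class Empty:
            lifespan_days = None

        with pytest.raises(ValueError):
            assign_lifespan_class(Empty())

    def test_movement_threshold_is_cohort_mean(self):
        recs = [record("a", distance=1), record("b", distance=2),
                record("c", distance=3), record("d", distance=10)]
        out = assign_movement_class(recs)
        assert out == {"a": "low", "b": "low", "c": "low", "d": "high"}

    def test_movement_ties_go_low(self):
        recs = [record("a", distance=5), record("b", distance=5)]
        assert set(assign_movement_class(recs).values()) == {"low"}

    def test_movement_two_records(self):
        recs = [record("a", distance=1), record("b", distance=3)]
        assert assign_movement_class(recs) == {"a": "low", "b": "high"}


class TestSplitByWormId:
    def test_130_worms_split_90_40(self):
        ids = [f"w{i}" for i in range(130)]
        split = split_by_worm_id(ids, 40 / 130, seed=0)
        assert len(split.test_ids) == 40
        assert len(split.train_ids) == 90
        assert not set(split.test_ids) & set(split.train_ids)

    def test_deterministic_under_seed(self):
        ids = [f"w{i}" for i in range(50)]
        a = split_by_worm_id(ids, 0.3, seed=5)
        b = split_by_worm_id(ids, 0.3, seed=5)
        assert a.assignment == b.assignment

    def test_duplicate_ids_collapse_to_one_side(self):
        split = split_by_worm_id(["a", "b", "a", "c", "d"], 0.4, seed=1)
        assert len(split.assignment) == 4

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_by_worm_id(["a", "b"], 0.01, seed=0)


class TestAugmentation:
    def test_epoch_yields_fold_times_n(self):
        rng = np.random.default_rng(0)
        imgs = [rng.random((8, 8)).astype(np.float32) for _ in range(4)]
        config = AugmentationConfig(fold=5, seed=1)
        pairs = list(augment_stream(imgs, [0, 1, 0, 1], config))
        assert len(pairs) == 20
        assert all(p[0].shape == (8, 8) for p in pairs)

    def test_zeroed_config_is_identity(self):
        rng = np.random.default_rng(0)
        imgs = [rng.random((8, 8)).astype(np.float32) for _ in range(3)]
        config = AugmentationConfig(horizontal_flip=False, vertical_flip=False,
                                    shift_fraction=0.0, rotation_range_deg=0.0,
                                    fold=2, seed=0)
        for k, (out, _) in enumerate(augment_stream(imgs, [0, 1, 2], config)):
            np.testing.assert_array_equal(out, imgs[k % 3])

    def test_double_flip_equals_index_reversal(self):
        grid = np.arange(64, dtype=np.float32).reshape(8, 8)
        config = AugmentationConfig(horizontal_flip=True, vertical_flip=True,
                                    shift_fraction=0.0, rotation_range_deg=0.0,
                                    fold=1, seed=0)

        class AlwaysFlip:
            def random(self):
                return 0.0  # < 0.5 -> both flips taken

        from wormsight.dataio import _transform_once

        out = _transform_once(grid, AlwaysFlip(), config)
        np.testing.assert_array_equal(out, grid[::-1, ::-1])

    def test_stream_deterministic_given_seed(self):
        imgs = [np.random.default_rng(3).random((8, 8)).astype(np.float32)]
        config = AugmentationConfig(fold=4, seed=9)
        a = [p for p, _ in augment_stream(imgs, [0], config)]
        b = [p for p, _ in augment_stream(imgs, [0], config)]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            AugmentationConfig(shift_fraction=1.5)
        with pytest.raises(ValueError):
            AugmentationConfig(fold=0)


class TestAblation:
    def _image(self, seed=0):
        return WormImage(np.random.default_rng(seed).random((16, 16)))

    def test_empty_mask_leaves_image_unchanged(self):
        img = self._image()
        out = ablate_worm(img, np.zeros((16, 16), bool), noise_seed=1)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_full_mask_gives_uniform_noise(self):
        img = WormImage(np.zeros((64, 64)) + 0.123)
        out = ablate_worm(img, np.ones((64, 64), bool), noise_seed=2)
        n = out.pixels.size
        # uniform(0,1): mean 0.5, sd 1/sqrt(12n)
        assert abs(out.pixels.mean() - 0.5) < 3.0 / np.sqrt(12 * n)

    def test_background_pixels_untouched(self):
        img = self._image(5)
        mask = np.zeros((16, 16), bool)
        mask[4:8, 4:8] = True
        out = ablate_worm(img, mask, noise_seed=3)
        np.testing.assert_array_equal(out.pixels[~mask], img.pixels[~mask])
        assert not np.array_equal(out.pixels[mask], img.pixels[mask])

    def test_mask_background_fill_and_complement(self):
        img = self._image(7)
        mask = np.zeros((16, 16), bool)
        mask[2:9, 3:12] = True
        assert np.array_equal(
            mask_background(img, np.ones((16, 16), bool), 0.0).pixels, img.pixels)
        filled = mask_background(img, np.zeros((16, 16), bool), 0.25)
        assert (filled.pixels == np.float32(0.25)).all()
        # keep-worm + keep-background reconstruct the original pixelwise
        worm_only = mask_background(img, mask, 0.0).pixels
        bg_only = np.where(mask, 0.0, img.pixels)
        np.testing.assert_allclose(worm_only + bg_only, img.pixels, atol=1e-7)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ablate_worm(self._image(), np.zeros((8, 8), bool), 0)
        with pytest.raises(ValueError):
            mask_background(self._image(), np.zeros((8, 8), bool), 0.0)


class TestMaskRoundtrip:
    def test_part_mask_set_invariants_and_io(self, tmp_path, small_cohort):
        masks = small_cohort.worms[0].masks
        assert masks.is_partition()
        write_mask_set(masks, tmp_path, "w0")
        back = read_mask_set(tmp_path, "w0")
        for name in ("anterior", "mid", "posterior", "whole"):
            np.testing.assert_array_equal(getattr(back, name), getattr(masks, name))
        label = masks.to_label_image()
        rebuilt = PartMaskSet.from_label_image(label)
        np.testing.assert_array_equal(rebuilt.whole, masks.whole)

    def test_dataset_directory_roundtrip(self, tmp_path, small_cohort):
        small_cohort.save(tmp_path / "ds")
        images, mask_sets, table = read_dataset_dir(tmp_path / "ds")
        assert images.shape == (len(small_cohort), 96, 96)
        np.testing.assert_allclose(images[0], small_cohort.worms[0].image,
                                   atol=1.0 / 65535)
        assert mask_sets[0].is_partition()
        assert list(table.worm_id) == [w.record.worm_id for w in small_cohort]
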