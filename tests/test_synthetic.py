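"""Synthetic dataset generation, augmentation, and raster I/O."""

import numpy as np
import pytest

from halfunet.synthetic import (
    DatasetManifest,
    SegmentationPair,
    SyntheticConfig,
    augment,
    augment_pair,
    generate,
    generate_arrays,
    load_arrays,
    read_pair,
    write_pair,
)


class TestGeneration:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = SyntheticConfig(regime="nodule", n_images=6, seed=42)
        m1 = generate(cfg, tmp_path / "a")
        m2 = generate(cfg, tmp_path / "b")
        for r1, r2 in zip(m1.records, m2.records):
            b1 = (tmp_path / "a" / r1.image).read_bytes()
            b2 = (tmp_path / "b" / r2.image).read_bytes()
            assert b1 == b2
            for k in r1.masks:
                assert (tmp_path / "a" / r1.masks[k]).read_bytes() \
                    == (tmp_path / "b" / r2.masks[k]).read_bytes()

    def test_noiseless_high_contrast_threshold_recovers_mask(self):
        cfg = SyntheticConfig(regime="mass", n_images=4, noise_sd=0.0,
                              background_gradient=False, edge_width=0.0,
                              texture=0.0, foreground_contrast=0.5, seed=3)
        x, masks = generate_arrays(cfg)
        for i in range(4):
            img = x[i, 0]
            thresh = (img.min() + img.max()) / 2.0
            np.testing.assert_array_equal((img > thresh).astype(np.uint8),
                                          masks["mask"][i, 0])

    def test_foreground_fraction_within_geometric_bounds(self):
        cfg = SyntheticConfig(regime="mass", n_images=8, seed=5).resolved()
        _, masks = generate_arrays(cfg)
        rmin, rmax = cfg.radius_range
        area = masks["mask"].sum(axis=(1, 2, 3)) / cfg.image_size**2
        upper = np.pi * rmax**2 / cfg.image_size**2 * 1.15
        lower = np.pi * (0.6 * rmin) * rmin / cfg.image_size**2 * 0.85
        assert np.all(area <= upper) and np.all(area >= lower)

    def test_ventricle_masks_nested(self):
        cfg = SyntheticConfig(regime="ventricle", n_images=3, seed=1,
                              image_size=128)
        _, masks = generate_arrays(cfg)
        endo, epi = masks["endocardium"], masks["epicardium"]
        assert np.all(epi >= endo)  # epicardial disc contains the cavity
        assert endo.sum() > 0

    def test_split_disjoint_seven_three(self, tmp_path):
        m = generate(SyntheticConfig(regime="nodule", n_images=10, seed=0),
                     tmp_path)
        assert len(m.split("train")) == 7 and len(m.split("test")) == 3
        assert not {r.image for r in m.split("train")} \
            & {r.image for r in m.split("test")}
        m.validate()

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(regime="mass", image_size=32,
                            radius_range=(10, 30)).resolved()


class TestAugmentation:
    def test_tenfold_expansion_of_training_split(self, tmp_path):
        m = generate(SyntheticConfig(regime="nodule", n_images=10, seed=0),
                     tmp_path)
        a = augment(m)
        assert len(a.split("train")) == 10 * len(m.split("train"))
        assert len(a.split("test")) == len(m.split("test"))
        assert sum(r.provenance == "augmented" for r in a.split("train")) \
            == 9 * len(m.split("train"))
        a.validate()

    def test_rotation_and_flip_group_identities(self, rng):
        img = (rng.random((32, 32)) * 255).astype(np.uint8)
        mask = np.zeros((32, 32), np.uint8)
        mask[8:14, 10:20] = 1
        variants = dict((t, (i, m)) for t, i, m in augment_pair(img, mask))
        # 180-degree rotation applied twice recovers the original exactly
        i180, m180 = variants["rot180"]
        np.testing.assert_array_equal(np.rot90(i180, 2), img)
        np.testing.assert_array_equal(np.rot90(m180, 2), mask)
        # flips are involutive and commute with the 180-degree rotation
        ih, mh = variants["hflip"]
        np.testing.assert_array_equal(np.fliplr(ih), img)
        # rot180 o hflip == vflip
        np.testing.assert_array_equal(np.rot90(mh, 2), variants["vflip"][1])

    def test_exact_area_preservation_at_right_angles(self, rng):
        mask = (rng.random((40, 40)) > 0.7).astype(np.uint8)
        variants = {t: m for t, _, m in
                    augment_pair(np.zeros((40, 40), np.uint8), mask)}
        for tag in ("rot90", "rot180", "rot270", "hflip", "vflip"):
            assert variants[tag].sum() == mask.sum()

    def test_area_tolerance_at_45_degrees(self):
        # object inside the inscribed circle, as the generator guarantees
        y, x = np.mgrid[0:64, 0:64]
        mask = ((x - 38.0) ** 2 + (y - 30.0) ** 2 <= 100).astype(np.uint8)
        variants = {t: m for t, _, m in
                    augment_pair(np.zeros((64, 64), np.uint8), mask)}
        for tag in ("rot45", "rot135", "rot225", "rot315"):
            rel = abs(int(variants[tag].sum()) - int(mask.sum())) / mask.sum()
            assert rel <= 0.05
            assert set(np.unique(variants[tag])) <= {0, 1}

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            augment_pair(np.zeros((8, 10), np.uint8), np.zeros((8, 10), np.uint8))


class TestRasterIO:
    @pytest.mark.parametrize("dtype", [np.uint8, np.uint16])
    def test_lossless_round_trip(self, tmp_path, rng, dtype):
        info = np.iinfo(dtype)
        img = (rng.random((17, 17)) * info.max).astype(dtype)
        mask = (rng.random((17, 17)) > 0.5).astype(np.uint8)
        write_pair(SegmentationPair(img, mask), tmp_path / "i.png",
                   tmp_path / "m.png")
        pair = read_pair(tmp_path / "i.png", tmp_path / "m.png")
        np.testing.assert_array_equal(pair.image, img)
        np.testing.assert_array_equal(pair.mask, mask)

    def test_single_foreground_pixel_survives(self, tmp_path):
        mask = np.zeros((9, 9), np.uint8)
        mask[4, 4] = 1
        write_pair(SegmentationPair(np.zeros((9, 9), np.uint8), mask),
                   tmp_path / "i.png", tmp_path / "m.png")
        assert read_pair(tmp_path / "i.png", tmp_path / "m.png").mask.sum() == 1

    def test_non_binary_mask_rejected(self, tmp_path):
        from PIL import Image

        arr = np.full((8, 8), 127, np.uint8)
        Image.fromarray(arr, mode="L").save(tmp_path / "bad.png")
        with pytest.raises(ValueError):
            read_pair(tmp_path / "bad.png", tmp_path / "bad.png")

    def test_load_arrays_scales_and_selects_target(self, tmp_path):
        m = generate(SyntheticConfig(regime="ventricle", n_images=3,
                                     image_size=64, seed=2), tmp_path)
        x, y = load_arrays(m, split="train", target="epicardium")
        assert x.dtype == np.float32 and x.max() <= 1.0
        assert set(np.unique(y)) <= {0.0, 1.0}
        assert x.shape == y.shape == (2, 1, 64, 64)
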