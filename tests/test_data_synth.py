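"""Synthetic generator, dataset I/O, splitting and augmentation."""

import numpy as np
import pytest

from dfdrnet.data_synth import (
    SamplePair,
    SynthConfig,
    augment,
    generate_dataset,
    generate_synthetic_sample,
    load_dataset,
    split_dataset,
    write_dataset,
)


class TestGenerator:
    def test_bitwise_reproducible(self):
        cfg = SynthConfig(seed=7)
        a = generate_synthetic_sample(cfg, 11)
        b = generate_synthetic_sample(cfg, 11)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.id == b.id

    def test_different_indices_differ(self):
        cfg = SynthConfig(seed=7)
        a = generate_synthetic_sample(cfg, 0)
        b = generate_synthetic_sample(cfg, 1)
        assert not np.array_equal(a.mask, b.mask) or not np.array_equal(a.image, b.image)

    def test_image_range_and_mask_binary(self):
        s = generate_synthetic_sample(SynthConfig(seed=3), 0)
        assert s.image.min() >= 0.0 and s.image.max() <= 1.0
        assert set(np.unique(s.mask)) <= {0, 1}

    def test_foreground_fraction_within_geometric_bounds(self):
        # expected per-lesion area ~ pi*a*b for semi-axes in [6, 18] on a
        # 64x64 frame; with 1-3 lesions the union stays well inside (1%, 60%)
        cfg = SynthConfig(seed=0)
        fracs = [generate_synthetic_sample(cfg, i).mask.mean() for i in range(100)]
        assert 0.05 < float(np.mean(fracs)) < 0.40
        assert min(fracs) > 0.005 and max(fracs) < 0.60

    def test_contrast_increases_lesion_background_separation(self):
        def separation(contrast):
            cfg = SynthConfig(seed=5, contrast=contrast, specular_density=0.0,
                              occlusion_prob=0.0)
            gaps = []
            for i in range(10):
                s = generate_synthetic_sample(cfg, i)
                if 0 < s.mask.mean() < 1:
                    g = s.image.mean(axis=2)
                    gaps.append(abs(g[s.mask == 1].mean() - g[s.mask == 0].mean()))
            return float(np.mean(gaps))

        assert separation(1.0) > separation(0.2)

    def test_specular_highlights_do_not_touch_mask(self):
        base = SynthConfig(seed=9, specular_density=0.0, occlusion_prob=0.0)
        dense = SynthConfig(seed=9, specular_density=25.0, occlusion_prob=0.0)
        for i in range(5):
            np.testing.assert_array_equal(
                generate_synthetic_sample(base, i).mask,
                generate_synthetic_sample(dense, i).mask,
            )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            SynthConfig(contrast=0.0).validate()
        with pytest.raises(ValueError, match="lesion_axes"):
            SynthConfig(lesion_axes=(10.0, 5.0)).validate()


class TestSplit:
    def test_thousand_samples_split_600_200_200(self):
        dummy = list(range(1000))
        tr, va, te = split_dataset(dummy, seed=0)
        assert (len(tr), len(va), len(te)) == (600, 200, 200)

    def test_small_set_disjoint_and_complete(self):
        items = [f"s{i}" for i in range(10)]
        tr, va, te = split_dataset(items, seed=4)
        assert (len(tr), len(va), len(te)) == (6, 2, 2)
        assert set(tr) | set(va) | set(te) == set(items)
        assert not (set(tr) & set(va)) and not (set(va) & set(te)) and not (set(tr) & set(te))

    def test_same_seed_reproduces_split(self):
        items = list(range(50))
        assert split_dataset(items, seed=3) == split_dataset(items, seed=3)

    def test_remainder_goes_to_train(self):
        tr, va, te = split_dataset(list(range(11)), seed=0)
        assert (len(tr), len(va), len(te)) == (7, 2, 2)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(list(range(10)), fractions=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError, match="at least 3"):
            split_dataset([1, 2])


class TestAugment:
    def test_geometry_applied_jointly(self, tiny_samples):
        # whatever flips were drawn, image and mask must agree: recover the
        # transform from the mask and check the image matches it
        s = tiny_samples[0]
        out = augment(s, seed=2)
        candidates = [
            (s.mask, s.image),
            (s.mask[:, ::-1], s.image[:, ::-1]),
            (s.mask[::-1], s.image[::-1]),
            (s.mask[::-1, ::-1], s.image[::-1, ::-1]),
        ]
        matched = False
        for m, img in candidates:
            if np.array_equal(out.mask, m):
                # photometric jitter is affine: image correlates with source
                flat_a, flat_b = out.image.ravel(), img.ravel()
                assert abs(np.corrcoef(flat_a, flat_b)[0, 1]) > 0.99
                matched = True
        assert matched, "augmented mask is not a flip of the source mask"

    def test_mask_stays_binary_and_image_in_range(self, tiny_samples):
        for seed in range(10):
            out = augment(tiny_samples[1], seed=seed, crop_size=24)
            assert set(np.unique(out.mask)) <= {0, 1}
            assert out.image.min() >= 0.0 and out.image.max() <= 1.0

    def test_fixed_seed_reproducible(self, tiny_samples):
        a = augment(tiny_samples[2], seed=77, crop_size=16)
        b = augment(tiny_samples[2], seed=77, crop_size=16)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_oversized_crop_rejected(self, tiny_samples):
        with pytest.raises(ValueError, match="crop_size"):
            augment(tiny_samples[0], seed=0, crop_size=999)


class TestIO:
    def test_write_then_load_roundtrip(self, tmp_path, tiny_samples):
        write_dataset(tiny_samples[:3], tmp_path)
        loaded = load_dataset(tmp_path / "images", tmp_path / "masks")
        assert [s.id for s in loaded] == sorted(s.id for s in tiny_samples[:3])
        by_id = {s.id: s for s in tiny_samples[:3]}
        for s in loaded:
            np.testing.assert_array_equal(s.mask, by_id[s.id].mask)
            # 8-bit quantization on write
            assert np.abs(s.image - by_id[s.id].image).max() < 1.0 / 255 + 1e-9

    def test_missing_mask_error_names_stem(self, tmp_path, tiny_samples):
        write_dataset(tiny_samples[:2], tmp_path)
        victim = sorted((tmp_path / "masks").iterdir())[0]
        stem = victim.stem
        victim.unlink()
        with pytest.raises(FileNotFoundError, match=stem):
            load_dataset(tmp_path / "images", tmp_path / "masks")

    def test_mask_values_binarized(self, tmp_path, tiny_samples):
        write_dataset(tiny_samples[:1], tmp_path)
        loaded = load_dataset(tmp_path / "images", tmp_path / "masks")
        assert set(np.unique(loaded[0].mask)) <= {0, 1}

    def test_missing_directory_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dataset(tmp_path / "nope", tmp_path / "nope2")


def test_sample_pair_validation():
    with pytest.raises(ValueError, match="mask"):
        SamplePair(image=np.zeros((4, 4, 3)), mask=np.zeros((5, 5)), id="x").validate()
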