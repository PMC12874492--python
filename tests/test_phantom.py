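"""Phantom generator: determinism, geometry, speckle, label jitter, splits."""

import numpy as np
import pytest
from scipy import ndimage

from mfsunet.errors import ConfigurationError, InvalidParameterError
from mfsunet.metrics import evaluate_masks
from mfsunet.phantom import (PhantomConfig, generate_dataset, generate_phantom,
                             jitter_label, read_dataset, write_dataset)


def small_cfg(**kw):
    base = dict(image_size=64)
    base.update(kw)
    return PhantomConfig(**base)


class TestGeneratePhantom:
    def test_bit_identical_for_same_seed(self):
        cfg = small_cfg()
        a = generate_phantom(cfg, 42)
        b = generate_phantom(cfg, 42)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.noisy_mask, b.noisy_mask)
        c = generate_phantom(cfg, 43)
        assert not np.array_equal(a.image, c.image)

    def test_noiseless_phantom_is_two_level_and_thresholdable(self):
        cfg = small_cfg(boundary_blur_sigma=0.0, speckle_strength=0.0,
                        shadow_prob=0.0, jitter_magnitude=0.0)
        s = generate_phantom(cfg, 5)
        assert len(np.unique(s.image)) == 2
        mid = cfg.background_level - cfg.contrast / 2
        assert np.array_equal(s.image < mid, s.mask)

    def test_nodule_darker_than_background(self):
        cfg = small_cfg()
        for seed in range(50):
            s = generate_phantom(cfg, seed)
            assert s.image[s.mask].mean() < s.image[~s.mask].mean()

    def test_mask_area_distribution(self):
        """Monte-Carlo audit: areas stay in the configured range (up to
        pixel quantisation) and the mean sits near the range midpoint."""
        cfg = small_cfg()
        areas = np.array([generate_phantom(cfg, i).mask.mean()
                          for i in range(300)])
        lo, hi = cfg.area_range
        quant = 2.0 / cfg.image_size   # one boundary-pixel ring of slack
        assert areas.min() >= lo - quant and areas.max() <= hi + quant
        mid = (lo + hi) / 2
        se = areas.std(ddof=1) / np.sqrt(len(areas))
        assert abs(areas.mean() - mid) < 3 * se + quant

    def test_infeasible_config_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(area_range=(0.3, 0.5), axis_ratio_range=(0.45, 1.0))
        with pytest.raises(ConfigurationError):
            PhantomConfig(area_range=(0.1, 0.05))


class TestJitterLabel:
    def test_zero_magnitude_is_identity(self, small_phantom):
        out = jitter_label(small_phantom.mask, 0.0, 99)
        assert np.array_equal(out, small_phantom.mask)

    def test_flips_confined_to_boundary_band(self, small_phantom):
        m = small_phantom.mask
        dist = np.where(m, ndimage.distance_transform_edt(m),
                        ndimage.distance_transform_edt(~m))
        for mag in (1.0, 2.0, 4.0):
            for seed in range(5):
                noisy = jitter_label(m, mag, seed)
                flipped = noisy != m
                if flipped.any():
                    assert dist[flipped].max() <= mag + 1e-9

    def test_dice_degrades_monotonically_on_average(self, small_phantom):
        m = small_phantom.mask
        mags = (0.0, 1.0, 2.0, 4.0)
        mean_dice = []
        for mag in mags:
            dices = [evaluate_masks(jitter_label(m, mag, s), m).dice
                     for s in range(50)]
            mean_dice.append(np.mean(dices))
        assert all(a >= b for a, b in zip(mean_dice, mean_dice[1:]))
        assert mean_dice[0] == 1.0

    def test_excessive_magnitude_warns(self, small_phantom):
        with pytest.warns(RuntimeWarning):
            jitter_label(small_phantom.mask, 1000.0, 0)

    def test_negative_magnitude_rejected(self, small_phantom):
        with pytest.raises(InvalidParameterError):
            jitter_label(small_phantom.mask, -1.0, 0)


class TestDataset:
    def test_patient_disjoint_splits(self):
        cfg = small_cfg(image_size=32)
        for seed in range(5):
            tr, va, te = generate_dataset(cfg, 60, seed=seed)
            sets = [{s.patient_id for s in split} for split in (tr, va, te)]
            assert sets[0] & sets[1] == set()
            assert sets[0] & sets[2] == set()
            assert sets[1] & sets[2] == set()
            assert all(sets)

    def test_split_sizes_near_ratios(self):
        tr, va, te = generate_dataset(small_cfg(image_size=32), 100, seed=1)
        n = len(tr) + len(va) + len(te)
        assert n == 100
        assert len(tr) >= 60          # up to patient-group granularity
        assert len(va) >= 5 and len(te) >= 5

    def test_same_seed_same_membership(self):
        cfg = small_cfg(image_size=32)
        a = generate_dataset(cfg, 40, seed=9)
        b = generate_dataset(cfg, 40, seed=9)
        for sa, sb in zip(a, b):
            assert [s.sample_id for s in sa] == [s.sample_id for s in sb]
            assert all(np.array_equal(x.image, y.image)
                       for x, y in zip(sa, sb))

    def test_bad_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_dataset(small_cfg(), 5)
        with pytest.raises(ConfigurationError):
            generate_dataset(small_cfg(), 20, split=(0.5, 0.2, 0.2))

    def test_disk_roundtrip(self, tmp_path):
        cfg = small_cfg(image_size=32)
        splits = generate_dataset(cfg, 20, seed=2)
        manifest = write_dataset(splits, tmp_path)
        assert len(manifest) == 20
        back = read_dataset(tmp_path)
        for name, orig in zip(("train", "val", "test"), splits):
            assert len(back[name]) == len(orig)
        s0, b0 = splits[0][0], back["train"][0]
        assert np.array_equal(s0.mask, b0.mask)
        assert np.array_equal(s0.noisy_mask, b0.noisy_mask)
        # image is 8-bit on disk
        assert np.abs(s0.image - b0.image).max() <= 0.5 / 255


class TestDifficultyKnob:
    def test_speckle_strength_degrades_a_fixed_segmenter(self):
        """A fixed non-learned segmenter (mid-level threshold + largest
        component) loses Dice as speckle grows: the generator spans
        easy-to-hard regimes."""
        def fixed_segmenter(img):
            thresh = img < (img.mean() - 0.5 * img.std())
            lab, n = ndimage.label(thresh)
            if n == 0:
                return thresh
            sizes = ndimage.sum(thresh, lab, index=range(1, n + 1))
            return lab == (1 + int(np.argmax(sizes)))

        mean_dice = []
        for strength in (0.0, 0.4, 1.2):
            cfg = small_cfg(speckle_strength=strength)
            dices = [evaluate_masks(fixed_segmenter(s.image), s.mask).dice
                     for s in (generate_phantom(cfg, i) for i in range(30))]
            mean_dice.append(np.mean(dices))
        assert mean_dice[0] > mean_dice[1] > mean_dice[2]
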