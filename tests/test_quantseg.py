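import numpy as np
import pytest
from skimage.draw import disk
from skimage.filters import threshold_multiotsu

from sonoquant.quantseg import (DegenerateInputError, RegionCriteria,
                                TriggerRule, otsu_thresholds, quantize,
                                refine_segmentation, select_lesion)
from sonoquant.segmetrics import mean_iou
from sonoquant.synthgen import PhantomSpec, make_phantom

N_BINS = 256


def brute_force_otsu(img, n):
    """Exhaustive between-class-variance maximization on the 256-bin
    histogram over [0, 1]; independent of the implementation under test."""
    hist, _ = np.histogram(img, bins=N_BINS, range=(0.0, 1.0))
    centers = (np.arange(N_BINS) + 0.5) / N_BINS
    w = hist.astype(float)

    def objective(cuts):
        # cuts: last bin index of each class except the final class
        bounds = [-1, *cuts, N_BINS - 1]
        total = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            wk = w[a + 1:b + 1].sum()
            if wk > 0:
                mk = (w[a + 1:b + 1] * centers[a + 1:b + 1]).sum() / wk
                total += wk * mk**2
        return total

    best, best_cuts = -1.0, None
    if n == 1:
        for i in range(N_BINS - 1):
            v = objective((i,))
            if v > best:
                best, best_cuts = v, (i,)
    elif n == 2:
        for i in range(N_BINS - 2):
            for j in range(i + 1, N_BINS - 1):
                v = objective((i, j))
                if v > best:
                    best, best_cuts = v, (i, j)
    else:
        raise NotImplementedError
    return (np.asarray(best_cuts, dtype=float) + 1.0) / N_BINS


class TestOtsuThresholds:
    def test_bimodal_single_threshold_separates(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((32, 32)) < 0.6, 0.2, 0.8)
        (t,) = otsu_thresholds(img, 1)
        assert 0.2 < t < 0.8

    def test_three_plateau_thresholds_match_exhaustive_search(self):
        rng = np.random.default_rng(1)
        img = rng.choice([0.1, 0.5, 0.9], size=(48, 48), p=[0.5, 0.3, 0.2])
        t = otsu_thresholds(img, 2)
        np.testing.assert_allclose(t, brute_force_otsu(img, 2))
        assert 0.1 < t[0] < 0.5 < t[1] < 0.9

    @pytest.mark.parametrize("n", [1, 2])
    def test_matches_brute_force_on_seeded_noise_images(self, n):
        # smooth blobby images exercise non-trivial histograms
        for seed in range(5):
            rng = np.random.default_rng(seed)
            img = rng.random((64, 64))
            img = np.clip(img * rng.uniform(0.5, 1.0) + rng.uniform(0, 0.3), 0, 1)
            np.testing.assert_allclose(otsu_thresholds(img, n),
                                       brute_force_otsu(img, n))

    def test_dp_path_matches_exhaustive_for_three_thresholds(self):
        # independent vectorized exhaustive n=3 oracle on one image
        rng = np.random.default_rng(3)
        img = rng.choice([0.05, 0.3, 0.55, 0.9], size=(64, 64),
                         p=[0.4, 0.3, 0.2, 0.1])
        hist, _ = np.histogram(img, bins=N_BINS, range=(0.0, 1.0))
        centers = (np.arange(N_BINS) + 0.5) / N_BINS
        w = np.concatenate([[0.0], np.cumsum(hist)])
        s = np.concatenate([[0.0], np.cumsum(hist * centers)])

        def term(a, b):  # class over bins a..b inclusive
            wk = w[b + 1] - w[a]
            sk = s[b + 1] - s[a]
            return np.where(wk > 0, sk**2 / np.where(wk > 0, wk, 1), 0.0)

        best, cuts = -1.0, None
        jj, kk = np.meshgrid(np.arange(N_BINS - 2), np.arange(N_BINS - 1),
                             indexing="ij")
        for i in range(N_BINS - 3):
            valid = (jj > i) & (kk > jj)
            obj = np.where(
                valid,
                term(0, i) + term(i + 1, jj) + term(jj + 1, kk)
                + term(kk + 1, N_BINS - 1),
                -np.inf,
            )
            m = obj.max()
            if m > best:
                best = m
                flat = int(np.argmax(obj))
                cuts = (i, flat // (N_BINS - 1), flat % (N_BINS - 1))
        expected = (np.asarray(cuts, dtype=float) + 1.0) / N_BINS
        np.testing.assert_allclose(otsu_thresholds(img, 3), expected)

    def test_agrees_with_reference_multiotsu_on_plateaus(self):
        rng = np.random.default_rng(5)
        img = rng.choice([0.15, 0.5, 0.85], size=(64, 64), p=[0.4, 0.35, 0.25])
        mine = quantize(img, otsu_thresholds(img, 2))
        ref = np.digitize(img, threshold_multiotsu(img, classes=3))
        np.testing.assert_array_equal(mine, ref)

    def test_degenerate_input_error_names_value_count(self):
        img = np.where(np.eye(8, dtype=bool), 0.2, 0.8)
        with pytest.raises(DegenerateInputError, match="2 distinct"):
            otsu_thresholds(img, 2)


class TestQuantize:
    def test_binary_thresholding_at_half(self, rng):
        img = rng.random((16, 16))
        levels = quantize(img, [0.5])
        np.testing.assert_array_equal(levels, (img >= 0.5).astype(int))

    def test_idempotent_on_piecewise_constant_input(self):
        rng = np.random.default_rng(2)
        parts = rng.choice([0, 1, 2], size=(40, 40), p=[0.4, 0.35, 0.25])
        img = np.choose(parts, [0.1, 0.5, 0.9])
        levels = quantize(img, otsu_thresholds(img, 2))
        np.testing.assert_array_equal(levels, parts)

    def test_class_mean_remap_minimizes_squared_error(self, rng):
        img = rng.random((32, 32))
        t = otsu_thresholds(img, 2)
        levels = quantize(img, t)
        means = np.array([img[levels == l].mean() for l in range(3)])
        err_mean = ((img - means[levels]) ** 2).sum()
        for _ in range(20):
            other = means + rng.normal(scale=0.05, size=3)
            assert ((img - other[levels]) ** 2).sum() >= err_mean

    def test_unsorted_thresholds_rejected(self, rng):
        with pytest.raises(ValueError):
            quantize(rng.random((4, 4)), [0.6, 0.3])


class TestSelectLesion:
    def test_dark_disk_recovered_without_coarse_mask(self):
        img = np.full((64, 64), 0.9)
        rr, cc = disk((32, 32), 12)
        img[rr, cc] = 0.1
        truth = np.zeros_like(img, dtype=np.uint8)
        truth[rr, cc] = 1
        levels = quantize(img, otsu_thresholds(img, 1))
        out = select_lesion(levels, img)
        assert mean_iou([out], [truth]) > 0.99

    def test_coarse_mask_disambiguates_spurious_region(self):
        img = np.full((64, 64), 0.8)
        rr, cc = disk((20, 20), 10)
        img[rr, cc] = 0.2  # the lesion
        img[50:60, 45:60] = 0.2  # spurious dark patch
        coarse = np.zeros_like(img, dtype=np.uint8)
        rr2, cc2 = disk((20, 20), 12)
        coarse[rr2, cc2] = 1
        levels = quantize(img, otsu_thresholds(img, 1))
        out = select_lesion(levels, img, coarse)
        assert out[20, 20] == 1
        assert out[55, 50] == 0

    def test_output_is_single_filled_component(self):
        img = np.full((48, 48), 0.85)
        rr, cc = disk((24, 24), 10)
        img[rr, cc] = 0.15
        img[24, 24] = 0.85  # poke a hole
        img[5:9, 5:9] = 0.15  # second component
        levels = quantize(img, otsu_thresholds(img, 1))
        out = select_lesion(levels, img)
        from scipy import ndimage

        _, n = ndimage.label(out, structure=np.ones((3, 3)))
        assert n == 1
        assert out[24, 24] == 1  # hole filled

    def test_min_area_filters_everything_returns_empty(self):
        img = np.full((32, 32), 0.9)
        img[4:6, 4:6] = 0.1
        levels = quantize(img, [0.5])
        out = select_lesion(levels, img, crit=RegionCriteria(min_area=100))
        assert out.sum() == 0


class TestRefineSegmentation:
    def test_pass_through_when_trigger_not_fired(self):
        sample = make_phantom(PhantomSpec(seed=11))
        out = refine_segmentation(sample.image, sample.mask)
        np.testing.assert_array_equal(out, sample.mask)

    def test_recovers_lesion_from_empty_coarse_mask(self):
        sample = make_phantom(PhantomSpec(seed=21))
        out = refine_segmentation(sample.image, np.zeros_like(sample.mask))
        assert mean_iou([out], [sample.mask]) >= 0.7

    def test_degenerate_image_returns_coarse_unchanged(self):
        img = np.where(np.eye(32, dtype=bool), 0.2, 0.8)
        coarse = np.zeros((32, 32), dtype=np.uint8)
        out = refine_segmentation(img, coarse, n=3, presmooth_sigma=0.0)
        np.testing.assert_array_equal(out, coarse)

    def test_low_solidity_coarse_mask_triggers(self):
        sample = make_phantom(PhantomSpec(seed=5))
        coarse = np.zeros_like(sample.mask)
        coarse[::2, ::8] = 1  # scattered, low-solidity guess
        fired, _ = TriggerRule().fires(coarse)
        assert fired
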