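import numpy as np
import pytest
from scipy import stats

from sonoquant.sunica import (IcaSaliencyExtractor, PatchConfig,
                              extract_patches, fit_ggd, fit_ica_model,
                              ggd_neg_log_pdf)


class TestExtractPatches:
    def test_constant_image_gives_zero_patches(self):
        img = np.full((32, 32), 0.4)
        patches = extract_patches([img], PatchConfig(patch_size=5, stride=3))
        np.testing.assert_allclose(patches, 0.0, atol=1e-12)

    def test_ramp_patches_have_zero_mean(self, rng):
        img = np.tile(np.linspace(0, 1, 64), (64, 1))
        patches = extract_patches([img], PatchConfig(patch_size=11, stride=4))
        np.testing.assert_allclose(patches.mean(axis=1), 0.0, atol=1e-12)

    def test_seeded_subsampling_is_deterministic(self, rng):
        imgs = [rng.random((40, 40)) for _ in range(3)]
        cfg = PatchConfig(patch_size=7, stride=1, max_patches=500, seed=9)
        np.testing.assert_array_equal(extract_patches(imgs, cfg),
                                      extract_patches(imgs, cfg))

    def test_image_smaller_than_patch_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_patches([rng.random((5, 5))], PatchConfig(patch_size=7))


class TestGgdFit:
    @pytest.mark.parametrize("beta_true,tol", [(1.0, 0.10), (2.0, 0.10)])
    def test_shape_recovery_within_ten_percent(self, beta_true, tol):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = stats.gennorm.rvs(beta_true, scale=1.3, size=10_000,
                                  random_state=rng)
            beta_hat, _ = fit_ggd(x)
            errs.append(abs(beta_hat - beta_true) / beta_true)
        assert np.mean(errs) < tol

    def test_scale_matches_variance_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(scale=2.0, size=50_000)
        beta, s = fit_ggd(x)
        # for beta ~ 2 the GGD scale is sqrt(2) * std
        assert s == pytest.approx(np.sqrt(2) * 2.0, rel=0.05)

    def test_neg_log_pdf_is_normalized_density(self):
        beta, s = 1.4, 0.7
        x = np.linspace(-20, 20, 200_001)
        pdf = np.exp(-ggd_neg_log_pdf(x, beta, s))
        assert np.trapezoid(pdf, x) == pytest.approx(1.0, abs=1e-6)


class TestIcaRecovery:
    def test_orthogonally_mixed_laplacian_sources_recovered(self):
        rng = np.random.default_rng(7)
        k, n = 8, 6000
        sources = rng.laplace(size=(n, k))
        mixing, _ = np.linalg.qr(rng.standard_normal((k, k)))
        patches = sources @ mixing.T
        model = IcaSaliencyExtractor(patch_size=3, k=k, drop_top=0,
                                     var_keep=1.0, seed=0)
        # bypass image patching: fit directly in the k-dim source space
        model.fit_patches(patches)
        recovered = patches @ (model.ica_filters_ @ model.pca_basis_).T
        corr = np.abs(np.corrcoef(sources.T, recovered.T)[:k, k:])
        assert np.all(corr.max(axis=1) >= 0.95)

    def test_too_few_patches_rejected(self, rng):
        with pytest.raises(ValueError, match="patches"):
            fit_ica_model(rng.standard_normal((50, 9)), k=8)


class TestSaliency:
    def test_constant_image_gives_flat_zero_map(self, fitted_extractor):
        sal = fitted_extractor.saliency_map(np.full((48, 48), 0.5))
        np.testing.assert_allclose(sal, 0.0, atol=1e-9)

    def test_joint_log_saliency_factorizes_over_filters(self, fitted_extractor,
                                                        phantom_set):
        """-log P(F) with P(F) = prod_i P(f_i) equals the per-filter sum."""
        img = phantom_set[0].image[:48, :48]
        model = fitted_extractor
        resp = model._responses(img)
        pdfs = np.exp(-np.stack([
            ggd_neg_log_pdf(resp[..., i], model.ggd_shape_[i], model.ggd_scale_[i])
            for i in range(model.n_filters_)
        ]))
        joint = -np.sum(np.log(pdfs), axis=0)
        sal = model.saliency_map(img)
        r = model.patch_size // 2
        interior = sal[r:-r, r:-r] + (joint.min() - sal[r:-r, r:-r].min())
        np.testing.assert_allclose(interior, joint, atol=1e-9)

    def test_invariant_to_constant_intensity_shift(self, fitted_extractor,
                                                   phantom_set):
        img = 0.3 + 0.4 * phantom_set[1].image[:48, :48]
        np.testing.assert_allclose(
            fitted_extractor.saliency_map(img),
            fitted_extractor.saliency_map(np.clip(img + 0.15, 0, 1)),
            atol=1e-8,
        )

    def test_oddball_patch_is_global_maximum(self, fitted_extractor):
        rows, cols = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        img = np.where((rows + cols) % 2 == 0, 0.45, 0.55)
        img[30:36, 30:36] = 1.0 - img[30:36, 30:36]  # inverted oddball
        sal = fitted_extractor.saliency_map(img)
        peak = np.unravel_index(np.argmax(sal), sal.shape)
        assert 24 <= peak[0] <= 41 and 24 <= peak[1] <= 41

    def test_model_round_trip_through_file(self, tmp_path, fitted_extractor,
                                           phantom_set):
        path = tmp_path / "model.npz"
        fitted_extractor.save(path)
        loaded = IcaSaliencyExtractor.load(path)
        img = phantom_set[2].image
        np.testing.assert_array_equal(fitted_extractor.saliency_map(img),
                                      loaded.saliency_map(img))


class TestFeatureVector:
    def test_unit_norm_for_nondegenerate_region(self, fitted_extractor,
                                                phantom_set):
        s = phantom_set[0]
        vec = fitted_extractor.feature_vector(s.image, s.mask)
        assert vec.shape == (fitted_extractor.n_filters_ + 1,)
        assert np.linalg.norm(vec) == pytest.approx(1.0, abs=1e-12)

    def test_depends_only_on_lesion_neighborhood(self, fitted_extractor,
                                                 phantom_set):
        s = phantom_set[3]
        far = s.image.copy()
        far[:8, :8] = 1.0 - far[:8, :8]  # corner well away from the lesion
        assert not np.array_equal(far, s.image)
        np.testing.assert_allclose(
            fitted_extractor.feature_vector(s.image, s.mask),
            fitted_extractor.feature_vector(far, s.mask),
            atol=1e-12,
        )

    def test_constant_region_returns_zero_vector_with_warning(
            self, fitted_extractor, caplog):
        img = np.full((48, 48), 0.5)
        mask = np.ones_like(img, dtype=np.uint8)
        with caplog.at_level("WARNING"):
            vec = fitted_extractor.feature_vector(img, mask)
        np.testing.assert_allclose(vec, 0.0, atol=1e-12)

    def test_empty_mask_rejected(self, fitted_extractor, phantom_set):
        s = phantom_set[0]
        with pytest.raises(ValueError, match="empty mask"):
            fitted_extractor.feature_vector(s.image, np.zeros_like(s.mask))
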