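"""Constrained unmixing: solver correctness, endmember derivation."""

import numpy as np
import pytest

import greencube as gc
from greencube.features import FeatureImage
from greencube.unmixing import EndmemberNotFoundError, EndmemberSet

from helpers import grid_search_unmix, simplex_grid


@pytest.fixture(scope="module")
def endmembers():
    truth = gc.default_scene(seed=0, shape=(8, 8))
    return EndmemberSet(truth.endmembers.feature_signatures(200))


class TestUnmixPixel:
    def test_pure_signature_recovers_vertex(self, endmembers):
        f, resid = gc.unmix_pixel(endmembers.signatures[0], endmembers)
        assert np.allclose(f, [1, 0, 0], atol=1e-9)
        assert resid == pytest.approx(0.0, abs=1e-9)

    def test_exact_half_mixture(self, endmembers):
        s = 0.5 * endmembers.signatures[0] + 0.5 * endmembers.signatures[1]
        f, resid = gc.unmix_pixel(s, endmembers)
        assert np.allclose(f, [0.5, 0.5, 0.0], atol=1e-9)

    def test_constraints_always_hold(self, endmembers):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = rng.uniform(-0.2, 1.0, 6)  # arbitrary, even unphysical signatures
            f, _ = gc.unmix_pixel(s, endmembers)
            assert f.min() >= -1e-12
            assert f.sum() == pytest.approx(1.0, abs=1e-9)

    def test_nonfinite_signature_gives_invalid(self, endmembers):
        f, resid = gc.unmix_pixel(np.array([0.1, np.nan, 0.2, 0.3, 0.1, 0.0]), endmembers)
        assert np.isnan(f).all() and np.isnan(resid)

    def test_matches_simplex_grid_oracle(self, endmembers):
        """Solver vs exhaustive grid search on >=100 noise-free mixtures."""
        C = endmembers.signatures
        grid = simplex_grid(1e-3)
        rng = np.random.default_rng(42)
        F = rng.dirichlet(np.ones(3), 100)
        S = F @ C
        max_vs_truth = 0.0
        max_vs_oracle = 0.0
        for s, f_true in zip(S, F):
            f, _ = gc.unmix_pixel(s, endmembers)
            f_oracle = grid_search_unmix(s, C, grid)
            max_vs_truth = max(max_vs_truth, np.abs(f - f_true).max())
            max_vs_oracle = max(max_vs_oracle, np.abs(f - f_oracle).max())
        assert max_vs_truth < 1e-6
        assert max_vs_oracle <= 2e-3  # within grid resolution


class TestCandidates:
    def _composite(self, ndvi, ndwi):
        ndvi = np.asarray(ndvi, float)
        bands = np.stack([np.full_like(ndvi, 0.2)] * 4 + [ndvi, np.asarray(ndwi, float)])
        return FeatureImage(bands=bands, valid=np.ones_like(ndvi, bool))

    def test_threshold_classes(self):
        comp = self._composite([[0.85, 0.15, 0.5]], [[-0.5, -0.1, 0.1]])
        masks = gc.select_endmember_candidates(comp)
        assert masks["vegetation"][0].tolist() == [True, False, False]
        assert masks["bare"][0].tolist() == [False, True, False]
        # NDVI 0.5, NDWI below threshold: candidate of no class
        assert not any(masks[k][0, 2] for k in masks)

    def test_water_by_ndwi(self):
        comp = self._composite([[-0.9]], [[0.8]])
        masks = gc.select_endmember_candidates(comp)
        assert masks["water"][0, 0]

    def test_bad_threshold_raises(self):
        comp = self._composite([[0.5]], [[0.0]])
        with pytest.raises(ValueError):
            gc.select_endmember_candidates(comp, ndvi_veg_min=1.5)


class TestDeriveSignatures:
    def test_identical_candidates_give_that_spectrum(self):
        sig_v = np.array([0.03, 0.08, 0.02, 0.78, 0.9, -0.8])
        sig_b = np.array([0.55, 0.43, 0.38, 0.42, 0.05, 0.01])
        sig_w = np.array([0.06, 0.83, 0.78, 0.02, -0.95, 0.95])
        bands = np.column_stack([sig_v, sig_b, sig_w]).reshape(6, 1, 3)
        comp = FeatureImage(bands=bands, valid=np.ones((1, 3), bool))
        masks = gc.select_endmember_candidates(comp)
        em = gc.derive_endmember_signatures(comp, masks, strategy="mean")
        assert np.allclose(em.signatures[0], sig_v)
        assert np.allclose(em.signatures[2], sig_w)

    def test_mean_strategy_averages_two_pixels(self):
        a = np.array([0.02, 0.08, 0.02, 0.80, 0.90, -0.8])
        b = np.array([0.04, 0.10, 0.04, 0.70, 0.86, -0.7])
        bare = np.array([0.55, 0.43, 0.38, 0.42, 0.05, 0.01])
        water = np.array([0.06, 0.83, 0.78, 0.02, -0.95, 0.95])
        bands = np.column_stack([a, b, bare, water]).reshape(6, 1, 4)
        comp = FeatureImage(bands=bands, valid=np.ones((1, 4), bool))
        masks = gc.select_endmember_candidates(comp)
        em = gc.derive_endmember_signatures(comp, masks, strategy="mean")
        assert np.allclose(em.signatures[0], (a + b) / 2)

    def test_recovers_generator_spectra_on_clean_scene(self, clean_result):
        truth, res = clean_result
        doy_peak = 198  # closest rendered date to the phenology peak
        expected = truth.endmembers.feature_signatures(doy_peak)
        assert np.abs(res.endmembers.signatures - expected).max() < 0.02

    def test_missing_class_raises_named_error(self):
        bands = np.full((6, 2, 2), 0.5)
        bands[4] = 0.5  # nothing passes any threshold
        comp = FeatureImage(bands=bands, valid=np.ones((2, 2), bool))
        masks = gc.select_endmember_candidates(comp)
        with pytest.raises(EndmemberNotFoundError, match="vegetation"):
            gc.derive_endmember_signatures(comp, masks)


class TestUnmixImage:
    def test_all_vegetation_scene(self, endmembers):
        sig = endmembers.signatures[0]
        bands = np.tile(sig[:, None, None], (1, 3, 3))
        comp = FeatureImage(bands=bands, valid=np.ones((3, 3), bool))
        fm = gc.unmix_image(comp, endmembers)
        assert np.allclose(fm.gmax, 1.0, atol=1e-6)

    def test_noise_free_round_trip_recovers_truth(self, clean_result):
        truth, res = clean_result
        err = np.nanmax(np.abs(res.fractions.fractions - truth.fractions))
        assert err < 1e-6

    def test_fractions_on_simplex_everywhere(self, noisy_result):
        _, res = noisy_result
        fm = res.fractions
        f = fm.fractions[:, fm.valid]
        assert f.shape[0] == 3
        assert f.min() >= -1e-12
        assert np.abs(f.sum(axis=0) - 1.0).max() < 1e-9

    def test_noise_robustness_rmse(self, noisy_result):
        """Reflectance noise sd 0.01 on the default scene: RMSE < 0.02."""
        truth, res = noisy_result
        rmse = np.sqrt(np.nanmean((res.fractions.fractions - truth.fractions) ** 2))
        assert rmse < 0.02

    def test_invalid_pixels_stay_invalid(self, endmembers):
        bands = np.tile(endmembers.signatures[0][:, None, None], (1, 2, 2))
        valid = np.array([[True, False], [True, True]])
        bands[:, ~valid] = np.nan
        comp = FeatureImage(bands=bands, valid=valid)
        fm = gc.unmix_image(comp, endmembers)
        assert np.isnan(fm.fractions[:, 0, 1]).all()
        assert not fm.valid[0, 1]
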