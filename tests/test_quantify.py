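"""GLCM contrast, ROI spectra, and per-band two-sample tests."""

import numpy as np
import pytest

from phsi import (
    GLCMConfig,
    ROIMask,
    SpectralAxis,
    StokesCube,
    extract_roi_spectra,
    glcm_contrast,
    per_band_ttest,
    rgb_to_gray,
)


def brute_force_contrast(image: np.ndarray, config: GLCMConfig) -> float:
    """Independent oracle: enumerate every in-bounds pixel pair directly."""
    levels = config.n_levels
    q = np.minimum((np.asarray(image, float) * levels).astype(int), levels - 1)
    rows, cols = q.shape
    counts = np.zeros((levels, levels))
    for dr, dc in config.directions:
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    counts[q[r, c], q[r2, c2]] += 1
                    if config.symmetric:
                        counts[q[r2, c2], q[r, c]] += 1
    p = counts / counts.sum()
    total = 0.0
    for i in range(levels):
        for j in range(levels):
            total += ((i - j) / (levels - 1)) ** 2 * p[i, j]
    return total


class TestGlcmContrast:
    def test_constant_image_scores_zero(self):
        assert glcm_contrast(np.full((10, 10), 0.4)) == 0.0

    def test_two_level_checkerboard_scores_one(self):
        img = np.indices((8, 8)).sum(axis=0) % 2
        config = GLCMConfig(n_levels=2, directions=((0, 1),))
        assert glcm_contrast(img.astype(float), config) == pytest.approx(1.0, abs=0)

    @pytest.mark.parametrize("symmetric", [True, False])
    @pytest.mark.parametrize("directions", [((0, 1),), ((0, 1), (1, 0), (1, 1), (1, -1))])
    def test_matches_brute_force_on_random_images(self, rng, symmetric, directions):
        config = GLCMConfig(n_levels=8, directions=directions, symmetric=symmetric)
        for _ in range(12):
            img = rng.uniform(size=(8, 8))
            assert glcm_contrast(img, config) == pytest.approx(
                brute_force_contrast(img, config), abs=1e-14
            )

    def test_invariant_to_gray_level_inversion(self, rng):
        config = GLCMConfig()  # symmetric by default
        img = rng.integers(0, 8, size=(12, 12)) / 8.0 + 1.0 / 16.0
        assert glcm_contrast(img, config) == pytest.approx(
            glcm_contrast(1.0 - img, config), abs=1e-14
        )

    def test_rejects_image_smaller_than_every_offset(self):
        with pytest.raises(ValueError, match="smaller"):
            glcm_contrast(np.zeros((1, 1)), GLCMConfig(directions=((0, 5),)))

    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValueError):
            glcm_contrast(np.full((4, 4), 1.5))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GLCMConfig(n_levels=1)
        with pytest.raises(ValueError):
            GLCMConfig(directions=((0, 0),))


class TestRgbToGray:
    @pytest.mark.parametrize("value,expected", [(1.0, 1.0), (0.0, 0.0), (0.37, 0.37)])
    def test_neutral_pixels_map_to_their_level(self, value, expected):
        img = np.full((3, 3, 3), value)
        np.testing.assert_allclose(rgb_to_gray(img), expected, atol=1e-12)

    def test_custom_weights_normalized(self):
        img = np.zeros((1, 1, 3))
        img[0, 0] = [1.0, 0.0, 0.0]
        assert rgb_to_gray(img, weights=(2, 1, 1)) == pytest.approx(0.5)


def _cube_from_band_values(axis, values, shape=(3, 3)):
    """Constant-per-band S0 cube with the other parameters zero."""
    data = np.broadcast_to(np.asarray(values, float), shape + (axis.n_bands,)).copy()
    zeros = np.zeros_like(data)
    return StokesCube(data, zeros, zeros, zeros, axis)


class TestExtractRoiSpectra:
    def test_single_pixel_roi_returns_that_spectrum(self, axis5, rng):
        data = rng.uniform(size=(4, 4, axis5.n_bands))
        cube = StokesCube(data, np.zeros_like(data), np.zeros_like(data),
                          np.zeros_like(data), axis5)
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True
        summary = extract_roi_spectra(cube, ROIMask(mask, "collagen"), "S0")
        np.testing.assert_allclose(summary.mean, data[1, 2])
        np.testing.assert_allclose(summary.std, 0.0, atol=1e-15)
        assert summary.label == "collagen"
        assert np.all(summary.n_pixels == 1)

    def test_all_true_mask_is_whole_image_mean(self, axis5, rng):
        data = rng.uniform(size=(5, 6, axis5.n_bands))
        cube = StokesCube(data, data, data, data, axis5)
        summary = extract_roi_spectra(cube, np.ones((5, 6), bool), "S2")
        np.testing.assert_allclose(summary.mean, data.mean(axis=(0, 1)))

    def test_two_pixel_population_std(self, axis5):
        a, b = 0.2, 0.8
        data = np.zeros((2, 1, axis5.n_bands))
        data[0, 0], data[1, 0] = a, b
        cube = StokesCube(data, np.zeros_like(data), np.zeros_like(data),
                          np.zeros_like(data), axis5)
        summary = extract_roi_spectra(cube, np.ones((2, 1), bool), "S0")
        np.testing.assert_allclose(summary.mean, (a + b) / 2)
        np.testing.assert_allclose(summary.std, abs(a - b) / 2)

    def test_means_linear_in_the_cube(self, axis5, rng):
        data = rng.normal(size=(4, 4, axis5.n_bands))
        zeros = np.zeros_like(data)
        mask = rng.uniform(size=(4, 4)) > 0.5
        mask[0, 0] = True
        s1 = extract_roi_spectra(StokesCube(data, zeros, zeros, zeros, axis5),
                                 mask, "S0")
        s2 = extract_roi_spectra(StokesCube(2.5 * data, zeros, zeros, zeros, axis5),
                                 mask, "S0")
        np.testing.assert_allclose(s2.mean, 2.5 * s1.mean, rtol=1e-12)

    def test_invalid_pixels_excluded(self, axis5):
        data = np.ones((2, 2, axis5.n_bands))
        valid = np.ones((2, 2, axis5.n_bands), bool)
        valid[0, 0] = False
        data[0, 0] = np.nan
        cube = StokesCube(data, data, data, data, axis5, normalized=True, valid=valid)
        summary = extract_roi_spectra(cube, np.ones((2, 2), bool), "S1")
        assert np.all(summary.n_pixels == 3)
        np.testing.assert_allclose(summary.mean, 1.0)

    def test_empty_effective_mask_rejected(self, axis5):
        data = np.ones((2, 2, axis5.n_bands))
        valid = np.zeros((2, 2, axis5.n_bands), bool)
        cube = StokesCube(data, data, data, data, axis5, normalized=True, valid=valid)
        with pytest.raises(ValueError, match="empty"):
            extract_roi_spectra(cube, np.ones((2, 2), bool), "S0")

    def test_empty_mask_rejected_at_construction(self):
        with pytest.raises(ValueError):
            ROIMask(np.zeros((3, 3), bool))


class TestPerBandTtest:
    def test_identical_groups_give_t0_p1(self, rng):
        spectra = [rng.uniform(size=6) for _ in range(4)]
        result = per_band_ttest(spectra, [s.copy() for s in spectra])
        np.testing.assert_allclose(result.t, 0.0, atol=1e-12)
        np.testing.assert_allclose(result.p, 1.0, atol=1e-12)

    def test_zero_variance_bands_report_p_one(self):
        a = [np.array([1.0, 2.0])] * 3
        b = [np.array([1.0, 5.0])] * 3
        result = per_band_ttest(a, b)
        assert result.p[0] == 1.0 and result.t[0] == 0.0

    def test_large_single_band_shift_detected(self, rng):
        """10 pooled SD at one band: closed-form Welch t is ~10*sqrt(n/2)."""
        n, bands = 5, 6
        a = [rng.normal(0, 1, size=bands) for _ in range(n)]
        b = [rng.normal(0, 1, size=bands) for _ in range(n)]
        for spec in b:
            spec[3] += 10.0
        result = per_band_ttest(a, b)
        assert result.p[3] < 0.05
        assert np.abs(result.t[3]) > 3.0

    def test_welch_matches_closed_form_on_two_point_groups(self):
        a = [np.array([0.0]), np.array([2.0])]
        b = [np.array([10.0]), np.array([14.0])]
        result = per_band_ttest(a, b, variant="welch")
        # Welch t = (1 - 12) / sqrt(2/2 + 8/2)
        expected_t = (1.0 - 12.0) / np.sqrt(2.0 / 2 + 8.0 / 2)
        assert result.t[0] == pytest.approx(expected_t, rel=1e-12)

    def test_p_values_within_unit_interval(self, rng):
        a = [rng.normal(size=8) for _ in range(5)]
        b = [rng.normal(size=8) for _ in range(5)]
        result = per_band_ttest(a, b, fdr=True)
        assert np.all((result.p >= 0) & (result.p <= 1))
        assert np.all((result.q >= 0) & (result.q <= 1))
        assert np.all(result.q >= result.p - 1e-12)

    def test_type_i_error_calibrated_under_null(self):
        """Rejection rate at alpha=0.05 under a seeded null is 0.05 +/- 0.02."""
        rng = np.random.default_rng(777)
        n_reps, n, bands = 200, 5, 8
        rejections = []
        for _ in range(n_reps):
            a = [rng.normal(size=bands) for _ in range(n)]
            b = [rng.normal(size=bands) for _ in range(n)]
            rejections.append(per_band_ttest(a, b).p < 0.05)
        rate = np.mean(rejections)
        assert 0.03 <= rate <= 0.07

    def test_retardance_difference_shows_in_s3_not_s0(self, axis21):
        """Cell phantoms whose tumor group differs from the normal group
        only in nuclear retardance: per-band p values for S3 fall below
        those for S0 (median over 10 seeded replicates)."""
        import phsi

        def spectrum(retardance, seed, parameter):
            params = phsi.CellPhantomParams(
                n_cells=1, nucleus_retardance_rad=retardance,
                nucleus_orientation_deg=10.0,
            )
            scene = phsi.make_cell_scene(params, (24, 24), axis21, seed=seed)
            images = phsi.simulate_acquisition(
                scene, noise=phsi.NoiseSpec(seed=seed + 1000))
            cube = phsi.normalize_stokes(phsi.compute_stokes(images))
            return extract_roi_spectra(cube, np.ones((24, 24), bool), parameter)

        medians = {"S0": [], "S3": []}
        for rep in range(10):
            for parameter in ("S0", "S3"):
                normal = [spectrum(0.05, rep * 100 + i, parameter) for i in range(5)]
                tumor = [spectrum(0.5, rep * 100 + 50 + i, parameter) for i in range(5)]
                medians[parameter].append(
                    np.median(per_band_ttest(normal, tumor).p))
        assert np.median(medians["S3"]) < np.median(medians["S0"])

    def test_groups_must_have_two_spectra(self):
        with pytest.raises(ValueError):
            per_band_ttest([np.zeros(3)], [np.zeros(3), np.ones(3)])

    def test_mismatched_band_grids_rejected(self):
        with pytest.raises(ValueError):
            per_band_ttest([np.zeros(3), np.ones(3)], [np.zeros(4), np.ones(4)])
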