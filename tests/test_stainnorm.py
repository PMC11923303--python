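"""Optical-density transforms and Macenko stain estimation/normalization."""

import numpy as np
import pytest

from tilscore.stainnorm import (
    DegenerateStainError,
    MacenkoParams,
    StainProfile,
    default_target_profile,
    estimate_stain_profile,
    normalize_patch,
    od_to_rgb,
    rgb_to_od,
    unmix_concentrations,
)
from tilscore.synthgen import PatchSpec, generate_patch, generate_stain_phantom

from conftest import angular_error_deg


class TestOpticalDensity:
    def test_background_intensity_maps_to_zero_od(self):
        od = rgb_to_od(np.full((1, 1, 3), 239, dtype=np.uint8), io=240)
        np.testing.assert_allclose(od, 0.0)

    def test_black_pixel_od_is_log_io(self):
        od = rgb_to_od(np.zeros((1, 1, 3), dtype=np.uint8), io=240)
        np.testing.assert_allclose(od, np.log(240.0), rtol=1e-12)

    def test_round_trip_within_one_intensity_unit(self):
        rng = np.random.default_rng(42)
        pixels = rng.integers(0, 240, (150, 150, 3)).astype(np.uint8)
        back = od_to_rgb(rgb_to_od(pixels))
        assert np.abs(back.astype(int) - pixels.astype(int)).max() <= 1

    def test_beer_lambert_concentration_recovery(self, target_profile):
        # unmixing a noiseless render with the true stain matrix recovers
        # the programmed concentrations up to 8-bit quantization
        pixels, c_h, c_e = generate_stain_phantom(seed=3, noise_sd=0.0)
        od = rgb_to_od(pixels, target_profile.io)
        conc = unmix_concentrations(od, target_profile.stain_matrix)
        rerendered = od_to_rgb(
            (target_profile.stain_matrix @ conc).T.reshape(pixels.shape),
            target_profile.io,
        )
        assert np.abs(rerendered.astype(int) - pixels.astype(int)).max() <= 2
        # concentration error from 8-bit quantization scales as 1/intensity;
        # the darkest phantom pixels (I ~ 20) bound it at ~1.5/20 OD units
        assert np.abs(conc[0] - c_h.ravel()).max() < 0.08
        assert np.abs(conc[1] - c_e.ravel()).max() < 0.08


class TestStainEstimation:
    def test_phantom_recovery_noiseless(self, reference_matrix):
        for seed in range(3):
            pixels, _, _ = generate_stain_phantom(seed=seed, noise_sd=0.0)
            profile = estimate_stain_profile(pixels)
            assert angular_error_deg(profile.hematoxylin, reference_matrix[:, 0]) <= 2.0
            assert angular_error_deg(profile.eosin, reference_matrix[:, 1]) <= 2.0

    def test_phantom_recovery_under_noise(self, reference_matrix):
        for seed in range(3):
            pixels, _, _ = generate_stain_phantom(seed=seed, noise_sd=8.0)
            profile = estimate_stain_profile(pixels)
            assert angular_error_deg(profile.hematoxylin, reference_matrix[:, 0]) <= 5.0
            assert angular_error_deg(profile.eosin, reference_matrix[:, 1]) <= 5.0

    def test_tissue_patch_recovery_noiseless(self, reference_matrix):
        patch, _, _ = generate_patch(
            PatchSpec(n_lymphocytes=3, n_tumor_cells=1, noise_sd=0.0, seed=2)
        )
        profile = estimate_stain_profile(patch)
        assert angular_error_deg(profile.hematoxylin, reference_matrix[:, 0]) <= 2.0
        assert angular_error_deg(profile.eosin, reference_matrix[:, 1]) <= 2.0

    def test_all_white_patch_is_degenerate(self):
        white = np.full((150, 150, 3), 255, dtype=np.uint8)
        with pytest.raises(DegenerateStainError):
            estimate_stain_profile(white)

    def test_single_stain_patch_is_degenerate(self, target_profile):
        # eosin only, spanning varied concentrations: angle percentiles
        # nearly coincide and the patch must be flagged
        conc = np.linspace(0.8, 2.0, 150 * 150).reshape(150, 150)
        od = conc[..., None] * target_profile.eosin
        pixels = od_to_rgb(od, target_profile.io)
        with pytest.raises(DegenerateStainError, match="single-stain"):
            estimate_stain_profile(pixels)

    def test_hematoxylin_column_has_larger_red_od(self):
        pixels, _, _ = generate_stain_phantom(seed=5)
        profile = estimate_stain_profile(pixels)
        assert profile.hematoxylin[0] > profile.eosin[0]


class TestNormalization:
    def test_fixed_point_when_already_in_target_profile(self):
        patch, _, _ = generate_patch(
            PatchSpec(n_lymphocytes=3, n_tumor_cells=1, noise_sd=0.0, seed=4)
        )
        own_profile = estimate_stain_profile(patch)
        result = normalize_patch(patch, target=own_profile)
        assert not result.passthrough
        change = np.abs(
            result.pixels.astype(float) - patch.pixels.astype(float)
        ).mean()
        assert change <= 2.0

    def test_idempotence_on_tissue_patches(self):
        for seed in (1, 5, 9):
            patch, _, _ = generate_patch(
                PatchSpec(n_lymphocytes=4, n_tumor_cells=2, noise_sd=0.0, seed=seed)
            )
            once = normalize_patch(patch)
            twice = normalize_patch(once.pixels)
            change = np.abs(once.pixels.astype(float) - twice.pixels.astype(float)).mean()
            assert change <= 2.0

    def test_normalization_aligns_differently_stained_copies(self, reference_matrix):
        # the same cell layout rendered with a perturbed stain matrix
        # converges to the target rendering after normalization
        rotated = np.array(
            [
                [0.70, 0.10],
                [0.60, 0.85],
                [0.39, 0.52],
            ]
        )
        rotated /= np.linalg.norm(rotated, axis=0)
        alt_profile = StainProfile(
            stain_matrix=rotated, max_concentration=[1.9705, 1.0308]
        )
        spec = PatchSpec(n_lymphocytes=4, n_tumor_cells=1, noise_sd=0.0, seed=6)
        patch_ref, _, _ = generate_patch(spec)
        patch_alt, _, _ = generate_patch(
            PatchSpec(**{**spec.__dict__, "stain_profile": alt_profile})
        )
        before = np.abs(
            patch_ref.pixels.astype(float) - patch_alt.pixels.astype(float)
        ).mean()
        norm_ref = normalize_patch(patch_ref).pixels.astype(float)
        norm_alt = normalize_patch(patch_alt).pixels.astype(float)
        after = np.abs(norm_ref - norm_alt).mean()
        assert after * 5.0 <= before

    def test_blank_patch_passes_through_with_flag(self):
        white = np.full((150, 150, 3), 255, dtype=np.uint8)
        result = normalize_patch(white)
        assert result.passthrough
        np.testing.assert_array_equal(result.pixels, white)

    def test_output_always_in_byte_range(self):
        patch, _, _ = generate_patch(
            PatchSpec(n_lymphocytes=5, n_tumor_cells=2, noise_sd=4.0, seed=8)
        )
        result = normalize_patch(patch)
        assert result.pixels.dtype == np.uint8
        assert result.pixels.min() >= 0 and result.pixels.max() <= 255


class TestStainProfileSerialization:
    def test_json_round_trip(self, tmp_path, target_profile):
        path = tmp_path / "profile.json"
        target_profile.to_json(path)
        loaded = StainProfile.from_json(path)
        np.testing.assert_allclose(loaded.stain_matrix, target_profile.stain_matrix)
        np.testing.assert_allclose(
            loaded.max_concentration, target_profile.max_concentration
        )
        assert loaded.io == target_profile.io

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            StainProfile(stain_matrix=np.ones((3, 2)), max_concentration=[1, 1])
        with pytest.raises(ValueError):
            StainProfile(
                stain_matrix=default_target_profile().stain_matrix,
                max_concentration=[0.0, 1.0],
            )
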