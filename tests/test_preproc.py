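"""Preprocessing chain: denoising, bias, registration, normalization, BET."""

from __future__ import annotations

import numpy as np
import pytest

from snipegrade.phantom import (
    add_noise,
    make_bias_field,
    make_pose_matrix,
    make_structure_volume,
    resample_affine,
    sample_pose,
)
from snipegrade.preproc import (
    BrainExtractionError,
    correct_bias,
    denoise_nlm,
    estimate_noise_sigma,
    extract_brain,
    normalize_intensity,
    preprocess_subject,
    register_affine,
)
from snipegrade.volume import Volume


class TestDenoise:
    def test_constant_volume_unchanged(self):
        vol = Volume(np.full((32, 32, 32), 7.0, dtype=np.float32))
        out = denoise_nlm(vol, h=1.0)
        np.testing.assert_allclose(out.data, 7.0, atol=1e-5)

    def test_reduces_background_noise(self, spec64):
        anat = make_structure_volume(spec64, 0.2, np.random.default_rng(1))
        rng = np.random.default_rng(2)
        noisy = add_noise(anat.image.data.astype(np.float64), spec64, rng)
        out = denoise_nlm(Volume(noisy.astype(np.float32)))
        bg = ~anat.brain_mask
        assert out.data[bg].std() < 0.5 * noisy[bg].std()

    def test_small_bandwidth_approaches_identity(self):
        rng = np.random.default_rng(3)
        noisy = (50 + rng.normal(0, 2, (24, 24, 24))).astype(np.float32)
        out = denoise_nlm(Volume(noisy), h=1e-4)
        assert np.abs(out.data - noisy).max() < 0.05

    def test_noise_estimate_tracks_truth(self):
        rng = np.random.default_rng(4)
        flat = 50 + rng.normal(0, 3.0, (48, 48, 48))
        assert estimate_noise_sigma(flat) == pytest.approx(3.0, rel=0.1)

    def test_nonfinite_input_rejected(self):
        bad = np.full((16, 16, 16), np.nan, dtype=np.float32)
        with pytest.raises(ValueError, match="finite"):
            denoise_nlm(Volume(bad))


class TestBiasCorrection:
    def test_unbiased_input_recovers_unit_field(self, spec64):
        anat = make_structure_volume(spec64, 0.0, rng=None)
        _, field = correct_bias(anat.image, anat.brain_mask, order=2)
        assert np.abs(field[anat.brain_mask] - 1.0).max() < 1e-6

    def test_known_order2_field_recovered(self, spec64):
        anat = make_structure_volume(spec64, 0.0, rng=None)
        rng = np.random.default_rng(5)
        true = make_bias_field(spec64, rng, anat.brain_mask)
        biased = Volume(anat.image.data * true)
        _, rec = correct_bias(biased, anat.brain_mask, order=2)
        m = anat.brain_mask
        rel_rmse = np.sqrt(np.mean((rec[m] - true[m]) ** 2)) / true[m].mean()
        assert rel_rmse < 0.05

    def test_multiplicative_identity(self, spec64):
        anat = make_structure_volume(spec64, 0.3, np.random.default_rng(6))
        corrected, field = correct_bias(anat.image, anat.brain_mask)
        np.testing.assert_allclose(
            corrected.data * field, anat.image.data, rtol=1e-10
        )

    def test_guards(self, spec64):
        anat = make_structure_volume(spec64, 0.0, rng=None)
        with pytest.raises(ValueError, match="order"):
            correct_bias(anat.image, anat.brain_mask, order=5)
        with pytest.raises(ValueError, match="empty"):
            correct_bias(anat.image, np.zeros_like(anat.brain_mask))
        zeros = Volume(np.zeros((64, 64, 64)))
        with pytest.raises(FloatingPointError):
            correct_bias(zeros, anat.brain_mask)


class TestRegistration:
    def test_self_registration_is_identity(self, template64):
        res = register_affine(template64.image, template64.image)
        pts = np.argwhere(template64.brain_mask)[::53].astype(float)
        pts_h = np.c_[pts, np.ones(len(pts))]
        disp = np.linalg.norm(pts_h @ res.transform.T - pts_h, axis=1)
        assert disp.mean() < 0.1
        assert res.converged

    def test_known_pose_recovery_fine(self, spec64, template64):
        pose = make_pose_matrix([3.0, 0.0, 0.0], [0.0, 3.0, 0.0], np.full(3, 31.5))
        moved = Volume(
            resample_affine(
                template64.image.data.astype(float), pose,
                cval=spec64.background_intensity,
            ).astype(np.float32)
        )
        res = register_affine(moved, template64.image, fine=True)
        pts = np.argwhere(template64.brain_mask)[::53].astype(float)
        pts_h = np.c_[pts, np.ones(len(pts))]
        err = np.linalg.norm(
            pts_h @ res.transform.T - pts_h @ np.linalg.inv(pose).T, axis=1
        )
        assert err.mean() < 0.5

    def test_output_grid_matches_template(self, spec64, template64):
        rng = np.random.default_rng(7)
        anat = make_structure_volume(spec64, 0.2, rng)
        moved = Volume(
            resample_affine(
                anat.image.data.astype(float), sample_pose(spec64, rng),
                cval=spec64.background_intensity,
            ).astype(np.float32),
        )
        res = register_affine(moved, template64.image, levels=2)
        assert res.resampled.shape == template64.image.shape
        assert res.resampled.voxel_size == template64.image.voxel_size == 1.0


class TestNormalization:
    def test_exact_linear_relation_recovered(self, template64):
        subj = Volume(2.0 * template64.image.data + 5.0)
        mask = np.ones(subj.shape, dtype=bool)
        out = normalize_intensity(subj, template64.image, mask)
        # implied (a, b) = (0.5, -2.5): output reproduces the template
        np.testing.assert_allclose(out.data, template64.image.data, atol=1e-4)

    def test_identity(self, template64):
        mask = np.ones(template64.image.shape, dtype=bool)
        out = normalize_intensity(template64.image, template64.image, mask)
        np.testing.assert_allclose(out.data, template64.image.data, atol=1e-4)

    def test_least_squares_reduces_residual(self, spec64, template64):
        rng = np.random.default_rng(8)
        anat = make_structure_volume(spec64, 0.1, rng)
        subj = Volume((1.7 * anat.image.data - 12).astype(np.float32))
        mask = anat.brain_mask
        out = normalize_intensity(subj, template64.image, mask)
        before = np.mean((subj.data[mask] - template64.image.data[mask]) ** 2)
        after = np.mean((out.data[mask] - template64.image.data[mask]) ** 2)
        assert after <= before

    def test_guards(self, template64):
        flat = Volume(np.full(template64.image.shape, 3.0))
        mask = np.ones(flat.shape, dtype=bool)
        with pytest.raises(ValueError, match="constant"):
            normalize_intensity(flat, template64.image, mask)
        with pytest.raises(ValueError, match="empty"):
            normalize_intensity(
                template64.image, template64.image, np.zeros_like(mask)
            )


class TestBrainExtraction:
    def test_noiseless_phantom_dice(self, spec64, library64):
        anat = make_structure_volume(spec64, 0.1, np.random.default_rng(9))
        mask = extract_brain(anat.image, library64)
        tru = anat.brain_mask
        dice = 2 * (mask & tru).sum() / (mask.sum() + tru.sum())
        assert dice >= 0.99

    def test_mask_binary_and_connected(self, spec64, library64):
        import scipy.ndimage as ndi

        anat = make_structure_volume(spec64, 0.4, np.random.default_rng(10))
        mask = extract_brain(anat.image, library64)
        assert mask.dtype == bool
        _, n_components = ndi.label(mask)
        assert n_components == 1

    def test_all_background_flagged(self, spec64, library64):
        flat = Volume(
            np.full((64, 64, 64), spec64.background_intensity, dtype=np.float32)
        )
        with pytest.raises(BrainExtractionError):
            extract_brain(flat, library64)


class TestFullChain:
    @pytest.fixture(scope="class")
    def corrupted(self, spec64):
        rng = np.random.default_rng(11)
        anat = make_structure_volume(spec64, 0.3, rng)
        bias = make_bias_field(spec64, rng, anat.brain_mask)
        pose = sample_pose(spec64, rng)
        img = add_noise(
            resample_affine(
                anat.image.data.astype(float) * bias, pose,
                cval=spec64.background_intensity,
            ),
            spec64,
            rng,
        )
        return anat, Volume(img.astype(np.float32))

    def test_deterministic(self, corrupted, template64, library64):
        _, vol = corrupted
        a = preprocess_subject(vol, template64.image, library64, template64.brain_mask)
        b = preprocess_subject(vol, template64.image, library64, template64.brain_mask)
        np.testing.assert_array_equal(a.volume.data, b.volume.data)
        np.testing.assert_array_equal(a.transform, b.transform)

    def test_second_pass_changes_less_than_first(
        self, corrupted, template64, library64
    ):
        """The chain is a contraction: reprocessing moves the volume less."""
        _, vol = corrupted
        p1 = preprocess_subject(vol, template64.image, library64, template64.brain_mask)
        p2 = preprocess_subject(
            p1.volume, template64.image, library64, template64.brain_mask
        )
        d01 = np.sqrt(np.mean((p1.volume.data - vol.data) ** 2))
        d12 = np.sqrt(np.mean((p2.volume.data - p1.volume.data) ** 2))
        assert d12 < d01

    def test_grid_preserved(self, corrupted, template64, library64):
        _, vol = corrupted
        res = preprocess_subject(
            vol, template64.image, library64, template64.brain_mask
        )
        assert res.volume.shape == template64.image.shape
        assert res.volume.voxel_size == 1.0
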