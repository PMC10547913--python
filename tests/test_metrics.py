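import numpy as np
import pytest

from pamfuse import (
    ValidationError,
    Volume,
    cross_entropy,
    cross_entropy_mean,
    depth_of_field,
    evaluate_fusion,
    fwhm_profile,
    snr_profile,
    spatial_frequency,
    ssim_total,
)
from pamfuse.metrics import DepthProfile

from oracles import cross_entropy_bruteforce, ssim_valid_window


def _ridge_volume(sigma_um=3.0, amplitude=1.0, shape=(9, 41, 12), pitch=2.0):
    """Gaussian ridge along y, centred, constant over x and z."""
    y = (np.arange(shape[1]) - shape[1] // 2) * pitch
    profile = amplitude * np.exp(-(y**2) / (2.0 * sigma_um**2))
    data = np.broadcast_to(profile[None, :, None], shape).copy()
    return Volume(data, spacing=(pitch, pitch, 3.0))


def _center_trajectory(v):
    traj = np.zeros((v.nz, 2))
    traj[:, 0] = v.shape[0] // 2
    traj[:, 1] = v.shape[1] // 2
    return traj


class TestFwhmProfile:
    def test_gaussian_ridge_recovers_known_width(self):
        v = _ridge_volume(sigma_um=3.0)
        profiles = fwhm_profile(v, _center_trajectory(v))
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * 3.0  # ~7.064 µm
        for p in profiles:
            assert p.valid
            assert abs(p.value - expected) <= v.spacing[1]

    def test_rectangular_profile_width(self):
        data = np.zeros((9, 21, 6))
        data[:, 8:13, :] = 1.0  # 5 samples wide at 2 µm pitch
        v = Volume(data, spacing=(2.0, 2.0, 3.0))
        profiles = fwhm_profile(v, _center_trajectory(v))
        for p in profiles:
            assert p.valid
            assert abs(p.value - 10.0) <= 1e-9

    def test_zero_plane_flagged_invalid(self):
        v = _ridge_volume()
        data = v.data.copy()
        data[:, :, 4] = 0.0
        profiles = fwhm_profile(Volume(data, v.spacing), _center_trajectory(v))
        assert not profiles[4].valid
        assert profiles[3].valid

    def test_subthreshold_peak_flagged_invalid(self):
        v = _ridge_volume()
        data = v.data.copy()
        data[:, :, 7] *= 0.01  # below the 5%-of-volume-max floor
        profiles = fwhm_profile(Volume(data, v.spacing), _center_trajectory(v))
        assert not profiles[7].valid

    def test_offcentre_peak_flagged_invalid(self):
        v = _ridge_volume()
        data = v.data.copy()
        data[:, :, 2] = 0.0
        data[4, 30, 2] = 1.0  # spurious peak far from the trajectory centre
        profiles = fwhm_profile(Volume(data, v.spacing), _center_trajectory(v),
                                window_halfwidth=None)
        assert not profiles[2].valid


class TestDepthOfField:
    @staticmethod
    def _profiles(values, dz=3.0, valid=None):
        valid = [True] * len(values) if valid is None else valid
        return [
            DepthProfile(z_index=i, z_um=i * dz, value=v, valid=ok)
            for i, (v, ok) in enumerate(zip(values, valid))
        ]

    def test_constant_fwhm_gives_full_depth_extent(self):
        profiles = self._profiles([5.0] * 21)
        assert depth_of_field(profiles, 10) == 20 * 3.0

    def test_hyperbolic_profile_matches_closed_form(self):
        # FWHM(z) = F0 sqrt(1 + ((z-zf)/a)^2) doubles at |z-zf| = a*sqrt(3)
        dz, zf, a, f0 = 1.0, 60, 20.0, 4.0
        z = np.arange(121) * dz
        values = f0 * np.sqrt(1.0 + ((z - zf * dz) / a) ** 2)
        dof = depth_of_field(self._profiles(values, dz=dz), zf)
        assert abs(dof - 2.0 * np.sqrt(3.0) * a) <= 0.05

    def test_invalid_planes_terminate_the_interval(self):
        values = [5.0] * 11
        valid = [True] * 11
        valid[2] = valid[8] = False
        dof = depth_of_field(self._profiles(values, valid=valid), 5)
        assert dof == (7 - 3) * 3.0

    def test_invariant_to_amplitude_rescaling(self, noiseless_study):
        from pamfuse.simulator import default_fiber_phantom, fiber_trajectory

        study = noiseless_study
        v = study.simulation.volumes[0]
        spec = default_fiber_phantom(diameter_um=study.diameter_um)
        traj = fiber_trajectory(spec, 0)
        scaled = Volume(13.7 * v.data, v.spacing)
        dof_a = depth_of_field(fwhm_profile(v, traj), study.focal_planes[0])
        dof_b = depth_of_field(fwhm_profile(scaled, traj), study.focal_planes[0])
        assert dof_a == dof_b

    def test_missing_focal_measurement_raises(self):
        profiles = self._profiles([5.0] * 5, valid=[True, True, False, True, True])
        with pytest.raises(ValidationError):
            depth_of_field(profiles, 2)


class TestSnrProfile:
    def test_twenty_db_by_definition(self, rng):
        data = rng.normal(0.0, 0.1, size=(21, 41, 8))
        data[10, 20, :] = 1.0
        v = Volume(data, spacing=(2.0, 2.0, 3.0))
        profiles = snr_profile(
            v, _center_trajectory(v), background_region=(slice(0, 5), slice(0, 41))
        )
        for p in profiles:
            assert p.valid
            assert abs(p.value - 20.0) <= 1.5

    def test_noiseless_background_flagged_invalid(self):
        data = np.zeros((9, 9, 4))
        data[4, 4, :] = 1.0
        v = Volume(data)
        profiles = snr_profile(
            v, _center_trajectory(v), background_region=(slice(0, 2), slice(0, 9))
        )
        assert not any(p.valid for p in profiles)


class TestCrossEntropy:
    def test_identical_images_give_zero(self, rng):
        img = rng.random((32, 32))
        assert cross_entropy(img, img) == 0.0

    def test_nonnegative_for_random_pairs(self, rng):
        for _ in range(5):
            a, b = rng.random((24, 24)), rng.random((24, 24))
            assert cross_entropy(a, b) >= 0.0

    def test_two_bin_hand_example(self):
        # p_src=(0.5,0.5), p_fused=(0.25,0.75) -> CE ~ 0.2075 bits
        src = np.concatenate([np.zeros(5000), np.ones(5000)]).reshape(100, 100)
        fus = np.concatenate([np.zeros(2500), np.ones(7500)]).reshape(100, 100)
        assert abs(cross_entropy(src, fus, bins=2) - 0.20752) <= 1e-3

    def test_matches_per_bin_loop(self, rng):
        a, b = rng.random((30, 30)), rng.random((30, 30))
        assert np.isclose(
            cross_entropy(a, b, bins=64), cross_entropy_bruteforce(a, b, 64)
        )

    def test_mean_over_both_sources(self, rng):
        s1, s2, f = (rng.random((16, 16)) for _ in range(3))
        expected = 0.5 * (cross_entropy(s1, f) + cross_entropy(s2, f))
        assert np.isclose(cross_entropy_mean(s1, s2, f), expected)


class TestSpatialFrequency:
    def test_constant_image_is_zero(self):
        assert spatial_frequency(np.full((8, 8), 3.0)) == 0.0

    def test_checkerboard_is_sqrt_two(self):
        board = np.indices((16, 16)).sum(axis=0) % 2
        assert np.isclose(spatial_frequency(board.astype(float)), np.sqrt(2.0))

    def test_depends_only_on_differences(self, rng):
        img = rng.random((20, 20))
        assert np.isclose(spatial_frequency(img + 7.5), spatial_frequency(img))

    def test_blurring_reduces_sf(self, rng):
        from scipy.ndimage import gaussian_filter

        img = rng.random((32, 32))
        assert spatial_frequency(gaussian_filter(img, 2.0)) < spatial_frequency(img)


class TestSsim:
    def test_identical_triplet_scores_two(self, rng):
        img = rng.random((32, 32))
        assert np.isclose(ssim_total(img, img, img), 2.0)

    def test_bounded_and_symmetric(self, rng):
        s1, s2, f = (rng.random((32, 32)) for _ in range(3))
        total = ssim_total(s1, s2, f)
        assert -2.0 < total <= 2.0
        assert np.isclose(total, ssim_total(s2, s1, f))

    def test_matches_valid_window_loop(self, rng):
        s, f = rng.random((32, 32)), rng.random((32, 32))
        data_range = float(max(s.max(), f.max()))
        from skimage.metrics import structural_similarity

        direct = structural_similarity(
            s, f, win_size=11, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03, data_range=data_range,
        )
        assert abs(direct - ssim_valid_window(s, f, data_range)) <= 1e-8

    def test_mean_mode_halves_the_sum(self, rng):
        s1, s2, f = (rng.random((24, 24)) for _ in range(3))
        assert np.isclose(
            ssim_total(s1, s2, f, mode="mean"), 0.5 * ssim_total(s1, s2, f)
        )


def test_evaluate_fusion_report_shape(noiseless_study):
    study = noiseless_study
    report = evaluate_fusion(
        study.fusion.fused, *study.simulation.volumes
    )
    assert report.ce >= 0.0
    assert report.sf > 0.0
    assert -2.0 < report.ssim_total <= 2.0
    assert report.qcv == "not computed"
    assert set(report.as_dict()) == {"ce", "sf", "ssim_total", "qcv"}
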