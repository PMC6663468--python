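"""Wedge masks, constrained correlation, alignment, Fourier averaging, FSC."""

import numpy as np
import pytest

from motoret.averaging import (
    FSCCurve,
    SearchSpec,
    align_particle,
    constrained_cc,
    fourier_average,
    fsc_between,
    refine_pose_local,
    resolution_at,
    split_half_fsc,
    wedge_mask,
)
from motoret._wedge import wedge_mask_array
from motoret.errors import UndefinedScoreError, ValidationError
from motoret.phantom_sim import WedgeSpec, apply_missing_wedge
from motoret.volume_io import Volume, apply_pose, euler_to_matrix


def _blob_volume(n=32, centers=((0, 0, 0),), sigma=2.5, voxel=1.0):
    z, y, x = np.indices((n, n, n), dtype=float) - n // 2
    data = np.zeros((n, n, n))
    for cx, cy, cz in centers:
        data += np.exp(-((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) / (2 * sigma**2))
    return Volume(data.astype(np.float32), voxel)


#: an asymmetric three-blob test object so rotations are identifiable
TRIPOD = ((6, 0, 0), (0, 9, 0), (-4, -4, 5))


class TestWedgeMask:
    def test_full_tilt_range_covers_everything(self):
        assert wedge_mask(WedgeSpec(-90, 90), (16, 16, 16)).all()

    def test_covered_fraction_within_nyquist_sphere_is_two_thirds(self):
        # solid-angle fraction of a +/-60 single-axis scheme is 120/180
        shape = (64, 64, 64)
        mask = wedge_mask(WedgeSpec(-60, 60), shape)
        kz = (np.fft.fftfreq(64))[:, None, None]
        ky = (np.fft.fftfreq(64))[None, :, None]
        kx = (np.fft.fftfreq(64))[None, None, :]
        ball = kx**2 + ky**2 + kz**2 <= 0.5**2
        assert mask[ball].mean() == pytest.approx(2 / 3, abs=0.02)

    def test_mask_is_hermitian_symmetric(self):
        mask = wedge_mask(WedgeSpec(-60, 40), (16, 18, 20))
        flipped = mask[::-1, ::-1, ::-1]
        flipped = np.roll(flipped, (1, 1, 1), axis=(0, 1, 2))  # conjugate-index map
        assert np.array_equal(mask, flipped)

    def test_dc_always_covered(self):
        assert wedge_mask(WedgeSpec(-10, 10), (16, 16, 16))[0, 0, 0]

    def test_rotated_mask_preserves_covered_solid_angle(self):
        # within the Nyquist sphere (cube corners are rotation-variant)
        rot = euler_to_matrix((30, 20, 10))
        shape = (32, 32, 32)
        m = wedge_mask_array(-60, 60, shape, rot_xyz=rot)
        assert m.dtype == bool and m[0, 0, 0]
        plain = wedge_mask_array(-60, 60, shape)
        k = np.fft.fftfreq(32)
        ball = (k[:, None, None] ** 2 + k[None, :, None] ** 2 + k[None, None, :] ** 2) <= 0.25
        assert abs(m[ball].mean() - plain[ball].mean()) < 0.03


class TestConstrainedCC:
    def test_self_correlation_is_one(self, rng):
        v = Volume(rng.normal(size=(32, 32, 32)), 1.0)
        w = WedgeSpec()
        assert constrained_cc(v, v, wedge_a=w, wedge_b=w) == pytest.approx(1.0, abs=1e-6)

    def test_negated_volume_scores_minus_one(self, rng):
        v = Volume(rng.normal(size=(32, 32, 32)), 1.0)
        assert constrained_cc(v, v.copy_with(-v.data)) == pytest.approx(-1.0, abs=1e-6)

    def test_independent_noise_scores_near_zero(self, rng):
        a = Volume(rng.normal(size=(64, 64, 64)), 1.0)
        b = Volume(rng.normal(size=(64, 64, 64)), 1.0)
        assert abs(constrained_cc(a, b)) < 0.05

    def test_grid_mismatch_rejected(self, rng):
        a = Volume(rng.normal(size=(16, 16, 16)), 1.0)
        b = Volume(rng.normal(size=(32, 32, 32)), 1.0)
        with pytest.raises(ValidationError):
            constrained_cc(a, b)

    def test_zero_spectral_power_raises_undefined_score(self):
        # a constant volume has no power off DC, so the score is undefined
        flat = Volume(np.ones((16, 16, 16), np.float32), 1.0)
        with pytest.raises(UndefinedScoreError):
            constrained_cc(flat, flat)


class TestAlignParticle:
    def test_identity_alignment_of_identical_volumes(self):
        ref = _blob_volume(centers=TRIPOD)
        search = SearchSpec(angular_grid_deg=2, max_axis_rot_deg=4, max_tilt_deg=2,
                            max_shift_voxels=1)
        (euler, shift), score = align_particle(ref, ref, search, WedgeSpec())
        assert score == pytest.approx(1.0, abs=1e-3)
        assert np.allclose(euler, 0, atol=1e-6) and np.allclose(shift, 0)

    def test_recovers_known_z_rotation_as_inverse(self):
        from motoret.averaging import _net_z_rotation

        ref = _blob_volume(centers=TRIPOD)
        particle = apply_pose(ref, (10.0, 0.0, 0.0), (0, 0, 0))
        search = SearchSpec(angular_grid_deg=2, max_axis_rot_deg=14, max_tilt_deg=2,
                            max_shift_voxels=1)
        (euler, _), _ = align_particle(particle, ref, search, WedgeSpec())
        assert _net_z_rotation(euler) == pytest.approx(-10.0, abs=1.0)

    def test_focused_cap_limits_z_rotation(self):
        from motoret.averaging import _net_z_rotation

        ref = _blob_volume(centers=TRIPOD)
        particle = apply_pose(ref, (6.0, 0.0, 0.0), (0, 0, 0))  # beyond the cap
        search = SearchSpec(angular_grid_deg=1, max_axis_rot_deg=1.9, max_tilt_deg=1,
                            max_shift_voxels=1)
        (euler, _), _ = align_particle(particle, ref, search, WedgeSpec())
        assert abs(_net_z_rotation(euler)) < 2.0

    def test_noisy_pose_recovery_rate(self, rng):
        # at SNR 0.5, jitter within the search range: >= 90% within 2x grid step
        from motoret.averaging import _net_z_rotation

        ref = _blob_volume(n=32, centers=TRIPOD)
        wedge = WedgeSpec()
        search = SearchSpec(angular_grid_deg=2, max_axis_rot_deg=6, max_tilt_deg=0,
                            max_shift_voxels=1)
        var_sig = float(ref.data.var())
        ok = 0
        n_trials = 10
        for _ in range(n_trials):
            true_rot = rng.uniform(-5, 5)
            moved = apply_pose(ref, (true_rot, 0, 0), (0, 0, 0))
            wedged = apply_missing_wedge(moved, wedge)
            noisy = wedged.copy_with(
                wedged.data + rng.normal(0, np.sqrt(var_sig / 0.5), wedged.shape).astype(np.float32)
            )
            (euler, _), _ = align_particle(noisy, ref, search, wedge)
            if abs(_net_z_rotation(euler) + true_rot) <= 2 * search.angular_grid_deg:
                ok += 1
        assert ok >= 0.9 * n_trials


class TestRefinePoseLocal:
    def test_recovers_small_rigid_perturbation(self):
        ref = _blob_volume(n=48, centers=TRIPOD, sigma=3.0)
        moved = apply_pose(ref, (2.0, 1.0, -1.5), (1.0, -0.8, 0.5))
        (euler, shift), score = refine_pose_local(moved, ref)
        realigned = apply_pose(moved, euler, shift)
        resid = np.sqrt(np.mean((realigned.data - ref.data) ** 2))
        base = np.sqrt(np.mean((moved.data - ref.data) ** 2))
        assert resid < 0.3 * base
        assert score > 0.98


class TestFourierAverage:
    def test_single_particle_identity_pose_returns_wedge_filtered_self(self):
        vol = _blob_volume(centers=TRIPOD)
        wedge = WedgeSpec()
        avg = fourier_average([vol], [((0, 0, 0), (0, 0, 0))], wedge)
        expected = apply_missing_wedge(vol, wedge)
        assert np.allclose(avg.density.data, expected.data, atol=1e-5)
        assert avg.n_particles == 1

    def test_tilt_axis_rotations_spanning_180_degrees_fill_the_wedge(self):
        # rotations about the tilt axis sweep the wedge over the whole sphere;
        # (rotations about the beam axis would leave a 30-degree missing cone)
        vol = _blob_volume(centers=TRIPOD)
        wedge = WedgeSpec()  # tilt axis y
        angles = np.arange(0, 180, 15.0)
        particles = [apply_pose(vol, (0, a, 0), (0, 0, 0)) for a in angles]
        poses = [((0.0, -a, 0.0), (0.0, 0.0, 0.0)) for a in angles]
        avg = fourier_average(particles, poses, wedge)
        assert (avg.coverage > 0).mean() > 0.95

    def test_coverage_equals_sum_of_rotated_masks(self):
        vol = _blob_volume(n=16)
        wedge = WedgeSpec()
        poses = [((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)), ((45.0, 0.0, 0.0), (0.0, 0.0, 0.0))]
        avg = fourier_average([vol, vol], poses, wedge)
        expected = sum(
            wedge_mask_array(-60, 60, vol.shape, rot_xyz=euler_to_matrix(p[0])).astype(int)
            for p in poses
        )
        assert np.array_equal(avg.coverage, expected)

    def test_noise_averaging_rms_scales_inverse_sqrt_n(self, rng):
        phantom = _blob_volume(n=24, sigma=3.0)
        wedge = WedgeSpec()
        clean = apply_missing_wedge(phantom, wedge)
        sigma = float(phantom.data.std())
        rms = {}
        for n in (4, 16, 64):
            parts = [
                phantom.copy_with(phantom.data + rng.normal(0, sigma, phantom.shape)
                                  .astype(np.float32))
                for _ in range(n)
            ]
            poses = [((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))] * n
            avg = fourier_average(parts, poses, wedge)
            rms[n] = float(np.sqrt(np.mean((avg.density.data - clean.data) ** 2)))
        assert rms[16] == pytest.approx(rms[4] / 2, rel=0.2)
        assert rms[64] == pytest.approx(rms[16] / 2, rel=0.2)

    def test_equivariance_under_common_rotation(self):
        # rotating all particles and poses by one extra rotation rotates the average
        vol = _blob_volume(n=32, centers=TRIPOD, sigma=3.5)
        wedge = WedgeSpec()
        angles = [0.0, 40.0, 80.0]
        particles = [apply_pose(vol, (a, 0, 0), (0, 0, 0)) for a in angles]
        poses = [((-a, 0.0, 0.0), (0.0, 0.0, 0.0)) for a in angles]
        avg = fourier_average(particles, poses, wedge)
        g = 25.0
        poses_rot = [((-a + g, 0.0, 0.0), (0.0, 0.0, 0.0)) for a in angles]
        avg_rot = fourier_average(particles, poses_rot, wedge)
        from motoret.volume_io import rotate_about_z

        expected = rotate_about_z(avg.density, g)
        sl = np.s_[4:-4, 4:-4, 4:-4]
        err = np.sqrt(np.mean((avg_rot.density.data[sl] - expected.data[sl]) ** 2))
        # two trilinear resamplings plus wedge-edge ringing set the error floor
        assert err < 0.15 * np.sqrt(np.mean(expected.data[sl] ** 2))

    def test_zero_particles_rejected(self):
        with pytest.raises(ValidationError):
            fourier_average([], [], WedgeSpec())


class TestFSC:
    def test_duplicated_particle_gives_unit_fsc(self):
        vol = _blob_volume(centers=TRIPOD)
        particles = [vol] * 10
        poses = [((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))] * 10
        curve = split_half_fsc(particles, poses, WedgeSpec(), seed=0)
        covered = curve.correlation != 0
        assert np.allclose(curve.correlation[covered], 1.0, atol=1e-6)

    def test_pure_noise_fsc_fluctuates_about_zero(self, rng):
        particles = [Volume(rng.normal(size=(32, 32, 32)).astype(np.float32), 1.0)
                     for _ in range(16)]
        poses = [((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))] * 16
        curve = split_half_fsc(particles, poses, WedgeSpec(), seed=1)
        assert abs(np.mean(curve.correlation[4:])) < 0.1

    def test_half_label_swap_leaves_curve_unchanged(self, rng):
        # the estimator is symmetric in the two halves by construction
        parts = [Volume(rng.normal(size=(16, 16, 16)).astype(np.float32), 1.0)
                 for _ in range(6)]
        poses = [((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))] * 6
        a = fourier_average(parts[:3], poses[:3], WedgeSpec())
        b = fourier_average(parts[3:], poses[3:], WedgeSpec())
        c1 = fsc_between(a.density, b.density)
        c2 = fsc_between(b.density, a.density)
        assert np.allclose(c1.correlation, c2.correlation, atol=1e-12)

    def test_fewer_than_two_particles_rejected(self):
        vol = _blob_volume(n=16)
        with pytest.raises(ValidationError):
            split_half_fsc([vol], [((0, 0, 0), (0, 0, 0))], WedgeSpec())


class TestResolutionAt:
    def test_constant_unit_curve_returns_nyquist(self):
        curve = FSCCurve(shell_radii=np.linspace(0, 0.4, 17), correlation=np.ones(17))
        assert resolution_at(curve, 0.5) == pytest.approx(0.4)

    def test_step_curve_crossing_location(self):
        radii = np.linspace(0, 0.4, 17)
        corr = np.where(radii < 0.2, 1.0, 0.0)
        assert resolution_at(curve := FSCCurve(radii, corr), 0.5) == pytest.approx(0.2, abs=0.0126)

    def test_monotone_curve_matches_brute_force_scan(self):
        radii = np.linspace(0, 0.4, 41)
        corr = 1.0 / (1.0 + np.exp((radii - 0.17) / 0.02))
        got = resolution_at(FSCCurve(radii, corr), 0.5)
        # brute-force scan on a fine grid with the same linear interpolation
        fine = np.linspace(0, 0.4, 40001)
        interp = np.interp(fine, radii, corr)
        expected = fine[np.argmax(interp < 0.5)]
        assert got == pytest.approx(expected, abs=1e-4)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValidationError):
            resolution_at(FSCCurve(np.array([]), np.array([])), 0.5)
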