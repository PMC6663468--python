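"""Phantom geometry, occupancy sampling, missing wedge, and ensemble simulation."""

import math

import numpy as np
import pytest

from motoret import phantom_sim as ps
from motoret.errors import ValidationError
from motoret.phantom_sim import (
    PoseJitter,
    SimulationSpec,
    StrainConfig,
    WedgeSpec,
    apply_missing_wedge,
    build_motor_phantom,
    gaussian_blob_integral,
    sample_occupancy,
    simulate_ensemble,
    strain_presets,
    tilt_series_image_count,
)


class TestStrainPresets:
    def test_preset_table_matches_strain_biology(self):
        p = strain_presets()
        assert set(p) == {"WT", "D24E", "D24N", "dmotB", "CCCP"}
        assert all(c.n_cring == 46 and c.n_collar == 16 for c in p.values())
        assert p["WT"].cring_tilt_deg == 1.8 and p["WT"].stator_occupancy == 0.97
        assert p["D24E"].cring_tilt_deg == 3.2 and p["D24E"].stator_count == 10
        assert p["D24N"].cring_tilt_deg == 6.6 and p["D24N"].stator_count == 7
        assert p["dmotB"].cring_tilt_deg == 7.8 and p["dmotB"].stator_count == 0
        assert p["CCCP"].cring_tilt_deg == 5.1 and p["CCCP"].stator_count == 16

    @pytest.mark.parametrize(
        "name,top_diameter_nm",
        [("WT", 56.7), ("dmotB", 59.0)],
    )
    def test_top_diameter_closed_form(self, name, top_diameter_nm):
        # 2 * (28 + 11 * tan(tilt)) reproduces the published top diameters
        cfg = strain_presets()[name]
        assert 2 * cfg.cring_radius_top_nm == pytest.approx(top_diameter_nm, abs=0.1)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            StrainConfig(name="x", n_cring=2, stator_occupancy=0.5)
        with pytest.raises(ValidationError):
            StrainConfig(name="x", stator_occupancy=1.5)
        with pytest.raises(ValidationError):
            StrainConfig(name="x", stator_occupancy=0.5, stator_count=3)
        with pytest.raises(ValidationError):
            StrainConfig(name="x", stator_count=17)


class TestPhantom:
    def test_stator_density_is_local_to_the_stator_annulus(self, mini_strain):
        all_on = build_motor_phantom(mini_strain, np.ones(4, bool), 48, 1.0)
        all_off = build_motor_phantom(mini_strain, np.zeros(4, bool), 48, 1.0)
        diff = np.abs(all_on.data - all_off.data)
        xx, yy, _ = all_on.coordinate_grids_nm()
        r = np.sqrt(xx**2 + yy**2)
        annulus = np.abs(r - mini_strain.stator_ring_radius_nm) <= 4.5 * mini_strain.stator_sigma_nm
        assert diff[~annulus].max() < 1e-3 * diff.max()

    def test_collar_periodicity_of_fully_occupied_phantom(self, mini_strain):
        from motoret.volume_io import rotate_about_z

        vol = build_motor_phantom(mini_strain, np.ones(4, bool), 48, 1.0)
        rot = rotate_about_z(vol, 360.0 / mini_strain.n_collar)
        # compare away from the box edges where rotation wraps
        sl = np.s_[4:-4, 4:-4, 4:-4]
        err = np.sqrt(np.mean((rot.data[sl] - vol.data[sl]) ** 2))
        assert err < 0.03 * np.sqrt(np.mean(vol.data[sl] ** 2))

    @pytest.mark.parametrize("k", [1, 3])
    def test_density_integral_counts_stator_blobs(self, mini_strain, k):
        # closed-form Gaussian integral: adding k stators adds k blob integrals
        flags = np.zeros(4, bool)
        flags[:k] = True
        vs = 1.0
        with_k = build_motor_phantom(mini_strain, flags, 48, vs)
        without = build_motor_phantom(mini_strain, np.zeros(4, bool), 48, vs)
        measured = (with_k.data.sum() - without.data.sum()) * vs**3
        expected = k * gaussian_blob_integral(mini_strain.stator_sigma_nm)
        assert measured == pytest.approx(expected, rel=0.01)

    def test_oversized_geometry_rejected(self, mini_strain):
        with pytest.raises(ValidationError):
            build_motor_phantom(mini_strain, np.ones(4, bool), 24, 1.0)


class TestOccupancySampling:
    def test_probability_one_gives_all_sites(self):
        cfg = StrainConfig(name="x", stator_occupancy=1.0)
        assert sample_occupancy(cfg, 5, seed=0).all()

    def test_fixed_count_is_exact_per_motor(self):
        cfg = strain_presets()["D24E"]  # 10 of 16
        flags = sample_occupancy(cfg, 50, seed=3)
        assert (flags.sum(axis=1) == 10).all()

    def test_bernoulli_mean_matches_rate(self):
        cfg = StrainConfig(name="x", stator_occupancy=0.5)
        flags = sample_occupancy(cfg, 2000, seed=7)
        se = math.sqrt(0.5 * 0.5 / flags.size)
        assert abs(flags.mean() - 0.5) < 3 * se


class TestMissingWedge:
    def test_near_full_tilt_range_changes_nothing(self, rng):
        from motoret.volume_io import Volume

        vol = Volume(rng.normal(size=(32, 32, 32)).astype(np.float32), 1.0)
        out = apply_missing_wedge(vol, WedgeSpec(-90, 90))
        assert np.allclose(out.data, vol.data, atol=1e-4)

    def test_wedge_projection_is_idempotent(self, rng):
        from motoret.volume_io import Volume

        vol = Volume(rng.normal(size=(32, 32, 32)).astype(np.float32), 1.0)
        once = apply_missing_wedge(vol, WedgeSpec())
        twice = apply_missing_wedge(once, WedgeSpec())
        assert np.allclose(twice.data, once.data, atol=1e-5)

    def test_white_noise_energy_ratio_equals_covered_fraction(self, rng):
        # Parseval: energy after wedge filtering / before = covered voxel fraction
        from motoret.volume_io import Volume
        from motoret.averaging import wedge_mask

        vol = Volume(rng.normal(size=(48, 48, 48)).astype(np.float32), 1.0)
        out = apply_missing_wedge(vol, WedgeSpec())
        ratio = float(np.sum(out.data**2) / np.sum(vol.data**2))
        grid_fraction = float(wedge_mask(WedgeSpec(), vol.shape).mean())
        assert ratio == pytest.approx(grid_fraction, abs=0.02)

    def test_tilt_series_image_count(self):
        # -60..60 in 2-degree steps acquires 61 images
        assert tilt_series_image_count(WedgeSpec(-60, 60), 2.0) == 61
        with pytest.raises(ValidationError):
            tilt_series_image_count(WedgeSpec(-60, 60), -1.0)


class TestSimulateEnsemble:
    def _mini_spec(self, mini_strain, **kw):
        defaults = dict(strain=mini_strain, n_motors=2, box_voxels=48, voxel_size_nm=1.0,
                        snr=0.5, seed=11)
        defaults.update(kw)
        return SimulationSpec(**defaults)

    def test_noiseless_zero_jitter_equals_wedged_phantom(self, mini_strain):
        spec = self._mini_spec(mini_strain, snr=np.inf, pose_jitter=PoseJitter(0, 0))
        stack, _, truth = simulate_ensemble(spec)
        phantom = build_motor_phantom(mini_strain, truth.occupancy_flags[0], 48, 1.0)
        wedged = apply_missing_wedge(phantom, spec.wedge)
        rms = np.sqrt(np.mean((stack[0] - wedged.data) ** 2))
        assert rms < 1e-6 * np.sqrt(np.mean(wedged.data**2))

    def test_same_seed_is_bit_identical(self, mini_strain):
        s1, t1, g1 = simulate_ensemble(self._mini_spec(mini_strain))
        s2, t2, g2 = simulate_ensemble(self._mini_spec(mini_strain))
        assert np.array_equal(s1, s2)
        assert t1 == t2
        assert np.array_equal(g1.occupancy_flags, g2.occupancy_flags)
        assert np.array_equal(g1.euler_deg, g2.euler_deg)

    def test_realized_noise_variance_matches_snr(self, mini_strain):
        spec = self._mini_spec(mini_strain, n_motors=1, pose_jitter=PoseJitter(0, 0))
        stack, _, truth = simulate_ensemble(spec)
        phantom = build_motor_phantom(mini_strain, truth.occupancy_flags[0], 48, 1.0)
        wedged = apply_missing_wedge(phantom, spec.wedge)
        mask = ps.signal_mask(wedged, mini_strain)
        noise = stack[0] - wedged.data
        expected_var = wedged.data[mask].var() / spec.snr
        assert noise.var() == pytest.approx(expected_var, rel=0.05)

    def test_box_too_small_rejected(self, mini_strain):
        with pytest.raises(ValidationError):
            self._mini_spec(mini_strain, box_voxels=32)

    def test_ground_truth_flags_match_realized_occupancy(self, mini_strain):
        _, _, truth = simulate_ensemble(self._mini_spec(mini_strain, n_motors=4))
        assert truth.realized_occupancy == truth.occupancy_flags.mean()
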