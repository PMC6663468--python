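"""Shared fixtures.

The heavy session-scoped fixtures simulate the full-scale (32-motor,
SNR 0.5) ensembles once and share them between the occupancy, tilt-ordering
and acceptance tests; unit tests use small custom geometries instead.
"""

from __future__ import annotations

import numpy as np
import pytest

from motoret import phantom_sim as ps
from motoret.averaging import refine_pose_local
from motoret.phantom_sim import PoseJitter, SimulationSpec, StrainConfig, WedgeSpec
from motoret.volume_io import Volume


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def mini_strain():
    """A small motor (8-fold C-ring, 4 sites) that fits a 48-voxel box."""
    return StrainConfig(
        name="mini",
        n_cring=8,
        n_collar=4,
        cring_radius_bottom_nm=10.0,
        cring_wall_height_nm=6.0,
        cring_tilt_deg=10.0,
        cring_z_bottom_nm=-10.0,
        stator_ring_radius_nm=16.0,
        stator_z_nm=-1.0,
        stator_occupancy=1.0,
        blob_sigma_nm=1.0,
        stator_sigma_nm=1.8,
        collar_sigma_nm=1.5,
        collar_radius_nm=16.0,
        collar_z_nm=6.0,
        membrane_z_nm=3.0,
        membrane_thickness_nm=3.0,
    )


@pytest.fixture(scope="session")
def wt_phantom():
    """Noiseless fully-occupied WT-preset phantom on the default grid."""
    strain = ps.strain_presets()["WT"]
    return ps.build_motor_phantom(strain, np.ones(strain.n_collar, bool), 96, 1.25)


def _simulate_and_register(name: str, n_motors: int = 32, snr: float = 0.5, seed: int = 42):
    strain = ps.strain_presets()[name]
    spec = SimulationSpec(strain=strain, n_motors=n_motors, snr=snr, seed=seed)
    stack, table, truth = ps.simulate_ensemble(spec)
    full = ps.build_motor_phantom(strain, np.ones(strain.n_collar, bool),
                                  spec.box_voxels, spec.voxel_size_nm)
    empty = ps.build_motor_phantom(strain, np.zeros(strain.n_collar, bool),
                                   spec.box_voxels, spec.voxel_size_nm)
    p = strain.mean_occupancy
    ref = ps.apply_missing_wedge(empty.copy_with(empty.data + p * (full.data - empty.data)),
                                 spec.wedge)
    vols = [Volume(stack[i], spec.voxel_size_nm) for i in range(n_motors)]
    poses = [refine_pose_local(v, ref)[0] for v in vols]
    return {"spec": spec, "vols": vols, "poses": poses, "truth": truth, "strain": strain}


@pytest.fixture(scope="session")
def wt_ensemble():
    return _simulate_and_register("WT")


@pytest.fixture(scope="session")
def d24e_ensemble():
    return _simulate_and_register("D24E")


@pytest.fixture(scope="session")
def d24n_ensemble():
    return _simulate_and_register("D24N")


@pytest.fixture(scope="session")
def dmotb_ensemble():
    return _simulate_and_register("dmotB")
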