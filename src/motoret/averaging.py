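"""Missing-wedge-aware alignment, Fourier-space averaging, and half-set FSC.

Every subtomogram carries a missing wedge: a cone of unsampled Fourier
space determined by the tilt range.  All comparisons and averages here are
therefore computed on Fourier supports:

* correlation scores are normalized only over the *intersection* of the two
  volumes' (pose-rotated) wedge supports ("constrained" cross-correlation);
* class averages are accumulated in Fourier space with a per-voxel coverage
  count, so that well-sampled regions are not diluted by unsampled ones;
* resolution is estimated by Fourier shell correlation between two
  randomly-split half-set averages.

Wedge supports are binary and evaluated analytically on the rotated
frequency grid, so pooled coverage counts are exact integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._wedge import wedge_mask_array
from .errors import UndefinedScoreError, ValidationError
from .phantom_sim import WedgeSpec
from .volume_io import Volume, apply_pose, euler_to_matrix, matrix_to_euler

__all__ = [
    "SearchSpec",
    "AverageMap",
    "FSCCurve",
    "wedge_mask",
    "constrained_cc",
    "align_particle",
    "fourier_average",
    "split_half_fsc",
    "resolution_at",
]


@dataclass
class SearchSpec:
    """Exhaustive-search settings for particle alignment.

    ``max_axis_rot_deg`` caps the rotation about the motor rod (z) axis —
    the focused-alignment restriction; ``max_tilt_deg`` bounds the two
    off-axis rotation parameters.  ``lowpass_cycles_per_voxel`` is the
    Gaussian low-pass applied to the reference during scoring.
    """

    angular_grid_deg: float = 2.0
    max_axis_rot_deg: float = 8.0
    max_tilt_deg: float = 4.0
    max_shift_voxels: int = 2
    mask: Volume | None = None
    lowpass_cycles_per_voxel: float = 0.25

    def __post_init__(self):
        if self.angular_grid_deg <= 0:
            raise ValidationError("angular_grid_deg must be positive")
        if not 0 < self.max_axis_rot_deg <= 180:
            raise ValidationError("max_axis_rot_deg must be in (0, 180]")
        if self.max_tilt_deg < 0:
            raise ValidationError("max_tilt_deg must be >= 0")
        if self.max_shift_voxels < 0:
            raise ValidationError("max_shift_voxels must be >= 0")


@dataclass
class AverageMap:
    """A density average with its per-voxel Fourier coverage."""

    density: Volume
    coverage: np.ndarray  # integer Fourier sample count, FFT layout
    n_particles: int


@dataclass
class FSCCurve:
    shell_radii: np.ndarray  # cycles/nm, one shell per Fourier voxel radius
    correlation: np.ndarray  # in [-1, 1]


def wedge_mask(wedge: WedgeSpec, shape) -> np.ndarray:
    """Binary Fourier-domain coverage mask in natural FFT layout.

    Hermitian-symmetric; DC (and the whole tilt-axis line) is covered.
    """
    return wedge_mask_array(wedge.tilt_min_deg, wedge.tilt_max_deg, shape, wedge.tilt_axis)


def _gaussian_lowpass(shape, cutoff_cycles_per_voxel: float) -> np.ndarray:
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    ky = np.fft.fftfreq(ny)[None, :, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    k2 = kx * kx + ky * ky + kz * kz
    return np.exp(-k2 / (2.0 * cutoff_cycles_per_voxel**2))


def constrained_cc(
    a: Volume,
    b: Volume,
    pose=None,
    wedge_a: WedgeSpec | None = None,
    wedge_b: WedgeSpec | None = None,
    mask: Volume | None = None,
) -> float:
    """Normalized cross-correlation over the intersection of wedge supports.

    ``pose = (euler_deg, shift_voxels)`` is applied to ``b`` before
    comparison; ``b``'s wedge support is rotated along with it.  The score
    is computed only on Fourier voxels sampled by *both* volumes (DC
    excluded) and lies in [-1, 1].
    """
    if a.shape != b.shape:
        raise ValidationError(f"grid mismatch: {a.shape} vs {b.shape}")
    b_t = b if pose is None else apply_pose(b, pose[0], pose[1])
    ones = np.ones(a.shape, dtype=bool)
    mask_a = ones if wedge_a is None else wedge_mask(wedge_a, a.shape)
    if wedge_b is None:
        mask_b = ones
    else:
        rot = None if pose is None else euler_to_matrix(pose[0])
        mask_b = wedge_mask_array(
            wedge_b.tilt_min_deg, wedge_b.tilt_max_deg, b.shape, wedge_b.tilt_axis, rot_xyz=rot
        )
    support = mask_a & mask_b
    support[0, 0, 0] = False
    if not support.any():
        raise UndefinedScoreError("empty wedge-support intersection")

    da = a.data.astype(np.float64)
    db = b_t.data.astype(np.float64)
    if mask is not None:
        da = da * mask.data
        db = db * mask.data
    fa = np.fft.fftn(da - da.mean())
    fb = np.fft.fftn(db - db.mean())
    num = float(np.sum((fa[support] * np.conj(fb[support])).real))
    den = float(np.sqrt(np.sum(np.abs(fa[support]) ** 2) * np.sum(np.abs(fb[support]) ** 2)))
    if den == 0:
        raise UndefinedScoreError("zero spectral power on the wedge intersection")
    return num / den


def _rotation_grid(search: SearchSpec, center=(0.0, 0.0, 0.0), step: float | None = None):
    """Candidate rotations around ``center``: z-rotation x two off-axis tilts.

    Yields ZYZ Euler triples in deterministic lexicographic order of the
    grid parameters ``(alpha_z, beta_x, gamma_y)``.
    """
    from scipy.spatial.transform import Rotation

    s = search.angular_grid_deg if step is None else step
    n_ax = int(np.floor(search.max_axis_rot_deg / s + 1e-9))
    n_tl = int(np.floor(search.max_tilt_deg / s + 1e-9))
    alphas = np.arange(-n_ax, n_ax + 1) * s
    betas = np.arange(-n_tl, n_tl + 1) * s
    r_center = euler_to_matrix(center)
    for da in alphas:
        for db_ in betas:
            for dg in betas:
                r = (
                    Rotation.from_euler("zxy", [da, db_, dg], degrees=True).as_matrix()
                    @ r_center
                )
                euler = matrix_to_euler(r)
                yield (da, db_, dg), euler, r


def align_particle(particle: Volume, reference: Volume, search: SearchSpec, wedge: WedgeSpec):
    """Exhaustive wedge-constrained alignment of one particle to a reference.

    Searches a grid of rotations (z-axis rotation capped by
    ``max_axis_rot_deg``, off-axis tilts by ``max_tilt_deg``) crossed with
    all integer shifts up to ``max_shift_voxels``, then refines the best
    rotation on a half-step local grid.  Returns ``((euler_deg,
    shift_voxels), score)``: the pose that maps the *particle* into the
    reference frame.  Deterministic; ties break toward the lexicographically
    smallest grid pose.
    """
    if particle.shape != reference.shape:
        raise ValidationError("particle and reference grids differ")
    shape = particle.shape
    ref = reference.data.astype(np.float64)
    ref = ref - ref.mean()
    if search.mask is not None:
        ref = ref * search.mask.data
    f_ref = np.fft.fftn(ref)
    if search.lowpass_cycles_per_voxel:
        f_ref = f_ref * _gaussian_lowpass(shape, search.lowpass_cycles_per_voxel)
    ms = search.max_shift_voxels

    def score_rotation(euler, rot):
        rotated = apply_pose(particle, euler, (0, 0, 0))
        d = rotated.data.astype(np.float64)
        if search.mask is not None:
            d = d * search.mask.data
        d = d - d.mean()
        fp = np.fft.fftn(d)
        support = wedge_mask_array(
            wedge.tilt_min_deg, wedge.tilt_max_deg, shape, wedge.tilt_axis, rot_xyz=rot
        )
        support[0, 0, 0] = False
        fa = f_ref * support
        fb = fp * support
        den = np.sqrt(np.sum(np.abs(fa) ** 2) * np.sum(np.abs(fb) ** 2))
        if den == 0:
            return -np.inf, (0, 0, 0)
        # correlation against all cyclic shifts of the rotated particle at once
        cc_map = np.fft.ifftn(fa * np.conj(fb)).real * np.prod(shape)
        best_val, best_shift = -np.inf, (0, 0, 0)
        for dz in range(-ms, ms + 1):
            for dy in range(-ms, ms + 1):
                for dx in range(-ms, ms + 1):
                    v = cc_map[dz % shape[0], dy % shape[1], dx % shape[2]]
                    if v > best_val:
                        best_val, best_shift = v, (dx, dy, dz)
        return best_val / den, best_shift

    best = None  # (score, grid_key, euler, shift)
    for key, euler, rot in _rotation_grid(search):
        sc, shift = score_rotation(euler, rot)
        if best is None or sc > best[0]:
            best = (sc, key, tuple(euler), shift)
    if best is None:
        raise ValidationError("empty search space")

    # one local refinement pass at half the angular step around the winner
    half = search.angular_grid_deg / 2.0
    center = best[2]
    refine = SearchSpec(
        angular_grid_deg=half,
        max_axis_rot_deg=half,
        max_tilt_deg=half,
        max_shift_voxels=ms,
        mask=search.mask,
        lowpass_cycles_per_voxel=search.lowpass_cycles_per_voxel,
    )
    for key, euler, rot in _rotation_grid(refine, center=center):
        # keep the z-rotation within the focused cap after refinement
        if abs(_net_z_rotation(euler)) > search.max_axis_rot_deg:
            continue
        sc, shift = score_rotation(euler, rot)
        if sc > best[0]:
            best = (sc, key, tuple(euler), shift)
    score, _, euler, shift = best
    return (tuple(np.round(euler, 6)), tuple(float(s) for s in shift)), float(score)


def _block_mean(data: np.ndarray, f: int) -> np.ndarray:
    nz, ny, nx = (s - s % f for s in data.shape)
    d = data[:nz, :ny, :nx]
    return d.reshape(nz // f, f, ny // f, f, nx // f, f).mean(axis=(1, 3, 5))


def refine_pose_local(
    particle: Volume,
    reference: Volume,
    max_euler_deg: float = 3.0,
    max_shift_voxels: float = 2.0,
    downsample: int = 2,
    x0=None,
) -> tuple:
    """Continuous local pose refinement by bounded Powell search on the
    real-space NCC of block-binned volumes.

    A fast complement to the exhaustive :func:`align_particle` for small
    residual pose errors (e.g. whole-motor registration before stator-site
    extraction): binning by ``downsample`` raises the per-voxel SNR and cuts
    the rotation cost, and the optimizer runs deterministically from the
    nominal pose.  Returns ``((euler_deg, shift_voxels), score)`` in
    full-resolution voxels, mapping the particle into the reference frame.
    """
    from scipy import optimize

    if particle.shape != reference.shape:
        raise ValidationError("particle and reference grids differ")
    f = max(1, int(downsample))
    p_small = Volume(
        _block_mean(particle.data.astype(np.float64), f), particle.voxel_size_nm * f
    )
    r_small = _block_mean(reference.data.astype(np.float64), f)
    r_small = r_small - r_small.mean()
    r_norm = np.linalg.norm(r_small)

    def neg_ncc(params):
        eul = params[:3]
        shift = params[3:] / f
        d = apply_pose(p_small, eul, shift).data.astype(np.float64)
        d = d - d.mean()
        den = r_norm * np.linalg.norm(d)
        if den == 0:
            return 0.0
        return -float(np.sum(r_small * d) / den)

    bounds = [(-max_euler_deg, max_euler_deg)] * 3 + [(-max_shift_voxels, max_shift_voxels)] * 3
    start = np.zeros(6) if x0 is None else np.asarray(x0, dtype=float)
    res = optimize.minimize(
        neg_ncc, start, method="Powell", bounds=bounds,
        options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 40},
    )
    euler = tuple(float(v) for v in res.x[:3])
    shift = tuple(float(v) for v in res.x[3:])
    return (euler, shift), float(-res.fun)


def _net_z_rotation(euler_deg) -> float:
    """In-plane (about z) rotation component of a ZYZ Euler triple, degrees."""
    r = euler_to_matrix(euler_deg)
    return float(np.degrees(np.arctan2(r[1, 0] - r[0, 1], r[0, 0] + r[1, 1])))


def fourier_average(particles, poses, wedge: WedgeSpec) -> AverageMap:
    """Fourier-space class average with per-voxel coverage normalization.

    Each particle is mapped into the common frame by its pose (the
    alignment result), its wedge support is rotated along with it, and the
    per-voxel Fourier sum is divided by the coverage count; voxels covered
    by no particle are zero.  The inverse transform is real.
    """
    particles = list(particles)
    poses = list(poses)
    if len(particles) == 0:
        raise ValidationError("need at least one particle")
    if len(poses) != len(particles):
        raise ValidationError("poses and particles differ in length")
    shape = particles[0].shape
    f_sum = np.zeros(shape, dtype=np.complex128)
    coverage = np.zeros(shape, dtype=np.int64)
    for vol, (euler, shift) in zip(particles, poses):
        if vol.shape != shape:
            raise ValidationError("all particles must share one grid")
        aligned = apply_pose(vol, euler, shift)
        support = wedge_mask_array(
            wedge.tilt_min_deg,
            wedge.tilt_max_deg,
            shape,
            wedge.tilt_axis,
            rot_xyz=euler_to_matrix(euler),
        )
        f_sum += np.fft.fftn(aligned.data.astype(np.float64)) * support
        coverage += support
    avg = np.where(coverage > 0, f_sum / np.maximum(coverage, 1), 0.0)
    density = np.fft.ifftn(avg).real.astype(np.float32)
    return AverageMap(
        density=particles[0].copy_with(density),
        coverage=coverage,
        n_particles=len(particles),
    )


def _shell_indices(shape):
    nz, ny, nx = shape
    kz = (np.fft.fftfreq(nz) * nz)[:, None, None]
    ky = (np.fft.fftfreq(ny) * ny)[None, :, None]
    kx = (np.fft.fftfreq(nx) * nx)[None, None, :]
    r = np.sqrt(kx * kx + ky * ky + kz * kz)
    return np.rint(r).astype(np.int64)


def fsc_between(map1: Volume, map2: Volume) -> FSCCurve:
    """Fourier shell correlation between two maps on one-voxel-wide shells."""
    if map1.shape != map2.shape:
        raise ValidationError("maps must share one grid")
    f1 = np.fft.fftn(map1.data.astype(np.float64))
    f2 = np.fft.fftn(map2.data.astype(np.float64))
    shells = _shell_indices(map1.shape)
    n_shell = min(map1.shape) // 2 + 1
    sel = shells < n_shell
    num = np.bincount(shells[sel], weights=(f1[sel] * np.conj(f2[sel])).real, minlength=n_shell)
    p1 = np.bincount(shells[sel], weights=np.abs(f1[sel]) ** 2, minlength=n_shell)
    p2 = np.bincount(shells[sel], weights=np.abs(f2[sel]) ** 2, minlength=n_shell)
    den = np.sqrt(p1 * p2)
    corr = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    box_nm = min(map1.shape) * map1.voxel_size_nm
    radii = np.arange(n_shell) / box_nm  # cycles/nm
    return FSCCurve(shell_radii=radii, correlation=corr)


def split_half_fsc(particles, poses, wedge: WedgeSpec, seed: int = 0) -> FSCCurve:
    """FSC between averages of two random (seeded) half-sets."""
    particles = list(particles)
    poses = list(poses)
    if len(particles) < 2:
        raise ValidationError("need at least two particles for a half-set split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(particles))
    half = len(particles) // 2
    idx1, idx2 = perm[:half], perm[half:]
    avg1 = fourier_average([particles[i] for i in idx1], [poses[i] for i in idx1], wedge)
    avg2 = fourier_average([particles[i] for i in idx2], [poses[i] for i in idx2], wedge)
    return fsc_between(avg1.density, avg2.density)


def resolution_at(curve: FSCCurve, threshold: float) -> float:
    """First (linearly interpolated) crossing of the FSC below ``threshold``,
    in cycles/nm; Nyquist if the curve never drops below it.  The DC shell
    is excluded from the search."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must be in (0, 1)")
    if len(curve.shell_radii) == 0:
        raise ValidationError("empty FSC curve")
    r = np.asarray(curve.shell_radii, dtype=float)
    c = np.asarray(curve.correlation, dtype=float)
    for i in range(1, len(c)):
        if c[i] < threshold:
            if i == 1:
                return float(r[1])
            frac = (c[i - 1] - threshold) / (c[i - 1] - c[i])
            return float(r[i - 1] + frac * (r[i] - r[i - 1]))
    return float(r[-1])
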