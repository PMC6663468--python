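"""Ring diameters, C-ring wall tilt via ellipse fitting, and cylindrical unrolling.

The tilt estimator follows the motor-structure measurement procedure:
apply 16-fold symmetry, take an axial cross-section, select the C-ring wall
density on each side of the rotation axis (excluding the FliG_N cap at the
top of the wall), fit an ellipse to the selected density, and report the
angle between the ellipse's long axis and the rotation axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InsufficientDensityError, ValidationError
from .volume_io import Volume

__all__ = [
    "RadialProfile",
    "EllipseFit",
    "TiltConfig",
    "TiltResult",
    "radial_profile",
    "measure_ring_diameter",
    "cring_tilt_angle",
    "unroll_map",
]


@dataclass
class RadialProfile:
    radii_nm: np.ndarray  # strictly increasing, >= 0
    density: np.ndarray  # mean density per radial bin within the z-slab

    def __post_init__(self):
        if np.any(self.radii_nm < 0) or np.any(np.diff(self.radii_nm) <= 0):
            raise ValidationError("radii must be non-negative and strictly increasing")


@dataclass
class EllipseFit:
    """Ellipse in an axial cross-section plane; the angle is measured between
    the major axis and the rotation (z) axis, in [0, 90] degrees."""

    center_nm: tuple  # (in-plane radial coordinate, z), nm
    semi_major_nm: float
    semi_minor_nm: float
    major_axis_angle_deg: float


@dataclass
class TiltConfig:
    """Settings for the symmetrize-then-ellipse-fit tilt measurement."""

    n_sym: int = 16
    r_window_nm: tuple = (24.0, 34.0)
    z_window_nm: tuple = (-14.0, -3.0)  # C-ring wall extent along the axis
    cap_exclusion_nm: float = 2.0  # FliG_N cap at the top of the wall
    density_quantile: float = 0.75
    slab_halfwidth_voxels: int = 1
    method: str = "moments"  # "moments" | "conic"
    min_voxels: int = 20


@dataclass
class TiltResult:
    tilt_deg: float
    side: str  # "mean" of the two walls
    fit_left: EllipseFit
    fit_right: EllipseFit
    quality_flag: bool = False  # True if the two walls disagree by > 2 deg


def radial_profile(vol: Volume, z_slab) -> RadialProfile:
    """Cylindrical average over theta and a z-slab, binned by radius (1-voxel bins).

    ``z_slab = (z_min_nm, z_max_nm)`` relative to the origin voxel.
    """
    z_min, z_max = z_slab
    if z_max <= z_min:
        raise ValidationError("z_slab must satisfy z_min < z_max")
    vs = vol.voxel_size_nm
    nz, ny, nx = vol.shape
    ox, oy, oz = vol.origin_voxel
    z_nm = (np.arange(nz) - oz) * vs
    planes = np.where((z_nm >= z_min) & (z_nm <= z_max))[0]
    if len(planes) == 0:
        raise ValidationError(f"z-slab {z_slab} contains no voxel plane")
    y = (np.arange(ny) - oy)[:, None] * vs
    x = (np.arange(nx) - ox)[None, :] * vs
    r = np.sqrt(x * x + y * y)
    bins = np.rint(r / vs).astype(int)
    slab = vol.data[planes].mean(axis=0).astype(np.float64)
    counts = np.bincount(bins.ravel())
    sums = np.bincount(bins.ravel(), weights=slab.ravel())
    density = sums / np.maximum(counts, 1)
    radii = np.arange(len(counts)) * vs
    return RadialProfile(radii_nm=radii, density=density)


def measure_ring_diameter(profile: RadialProfile, r_window) -> float:
    """Ring diameter (nm): twice the parabolically interpolated peak radius
    of the radial profile within ``r_window = (r_lo_nm, r_hi_nm)``."""
    r_lo, r_hi = r_window
    sel = np.where((profile.radii_nm >= r_lo) & (profile.radii_nm <= r_hi))[0]
    if len(sel) == 0:
        raise ValidationError(f"window {r_window} outside the profile")
    k = sel[np.argmax(profile.density[sel])]
    if k == sel[0] or k == sel[-1]:
        warnings.warn(
            f"radial-profile peak lies on the window boundary ({profile.radii_nm[k]:.2f} nm)",
            stacklevel=2,
        )
        return 2.0 * float(profile.radii_nm[k])
    # sub-bin parabolic interpolation through the peak and its neighbors
    y0, y1, y2 = profile.density[k - 1 : k + 2]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = profile.radii_nm[k + 1] - profile.radii_nm[k]
    return 2.0 * float(profile.radii_nm[k] + delta * step)


def _wall_points(cross, x_nm, z_nm, cfg: TiltConfig, side: int):
    """Select above-quantile wall voxels on one side (+1 right, -1 left)."""
    z_lo, z_hi = cfg.z_window_nm
    z_hi = z_hi - cfg.cap_exclusion_nm
    r_lo, r_hi = cfg.r_window_nm
    xx, zz = np.meshgrid(x_nm, z_nm, indexing="ij")
    region = (side * xx >= r_lo) & (side * xx <= r_hi) & (zz >= z_lo) & (zz <= z_hi)
    if not np.any(region):
        raise ValidationError("tilt window lies outside the volume")
    vals = cross[region]
    thr = np.quantile(vals, cfg.density_quantile)
    # soft selection: weight by the density excess over the threshold, so the
    # support boundary tapers smoothly instead of quantizing to the grid
    sel = region & (cross > thr)
    pts = np.column_stack([side * xx[sel], zz[sel]])  # radial coordinate, z
    w = (cross[sel] - thr).astype(np.float64)
    if len(pts) < cfg.min_voxels:
        raise InsufficientDensityError(
            f"only {len(pts)} voxels above the {cfg.density_quantile} quantile in the wall window"
        )
    return pts, w


def _ellipse_moments(pts: np.ndarray, weights: np.ndarray) -> EllipseFit:
    """Intensity-weighted second-moment ellipse of selected (radial, z) points."""
    w = weights / weights.sum()
    mu = w @ pts
    d = pts - mu
    cov = (d * w[:, None]).T @ d
    evals, evecs = np.linalg.eigh(cov)  # ascending
    major = evecs[:, 1]
    angle = np.degrees(np.arctan2(abs(major[0]), abs(major[1])))  # from the z axis
    return EllipseFit(
        center_nm=(float(mu[0]), float(mu[1])),
        semi_major_nm=2.0 * float(np.sqrt(max(evals[1], 0))),
        semi_minor_nm=2.0 * float(np.sqrt(max(evals[0], 0))),
        major_axis_angle_deg=float(angle),
    )


def _ellipse_conic(pts: np.ndarray, weights: np.ndarray) -> EllipseFit:
    """Weighted direct least-squares conic (ellipse-constrained) fit.

    Independent cross-check for the moments fit: solves the
    ellipse-specific generalized eigenproblem (4AC - B^2 = 1 constraint)
    on the weighted design matrix.
    """
    x, y = pts[:, 0], pts[:, 1]
    w = np.sqrt(weights / weights.sum())
    d1 = np.column_stack([x * x, x * y, y * y]) * w[:, None]
    d2 = np.column_stack([x, y, np.ones_like(x)]) * w[:, None]
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
        c1inv = np.array([[0.0, 0.0, 0.5], [0.0, -1.0, 0.0], [0.5, 0.0, 0.0]])
        m = c1inv @ (s1 + s2 @ t)
        evals, evecs = np.linalg.eig(m)
    except np.linalg.LinAlgError as exc:
        raise InsufficientDensityError(f"conic ellipse fit failed: {exc}") from exc
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.where(np.isreal(evals) & (cond.real > 0))[0]
    if len(ok) == 0:
        raise InsufficientDensityError("conic fit found no ellipse solution")
    a1 = evecs[:, ok[0]].real
    a2 = t @ a1
    a_, b_, c_, d_, e_, f_ = a1[0], a1[1], a1[2], a2[0], a2[1], a2[2]
    den = b_ * b_ - 4.0 * a_ * c_
    xc = (2.0 * c_ * d_ - b_ * e_) / den
    yc = (2.0 * a_ * e_ - b_ * d_) / den
    # quadratic-form eigendecomposition: the major axis is the eigenvector
    # of the smaller eigenvalue (sign-normalized to a positive-definite form)
    m33 = np.array([[a_, b_ / 2.0], [b_ / 2.0, c_]])
    if np.trace(m33) < 0:
        m33, a_, b_, c_, d_, e_, f_ = -m33, -a_, -b_, -c_, -d_, -e_, -f_
    q3 = np.array([[a_, b_ / 2.0, d_ / 2.0], [b_ / 2.0, c_, e_ / 2.0], [d_ / 2.0, e_ / 2.0, f_]])
    lam, vec = np.linalg.eigh(m33)  # ascending; lam[0] <-> major axis
    scale = -np.linalg.det(q3) / max(np.linalg.det(m33), 1e-300)
    semi = np.sqrt(np.maximum(scale / lam, 0.0))
    major = vec[:, 0]
    angle = np.degrees(np.arctan2(abs(major[0]), abs(major[1])))
    return EllipseFit(
        center_nm=(float(xc), float(yc)),
        semi_major_nm=float(semi[0]),
        semi_minor_nm=float(semi[1]),
        major_axis_angle_deg=float(angle),
    )


def cring_tilt_angle(vol: Volume, config: TiltConfig | None = None) -> TiltResult:
    """C-ring wall tilt from an n-fold-symmetrized axial cross-section.

    Procedure: symmetrize about the rotation axis; average a thin axial
    cross-section slab; per wall (left/right of the axis) select voxels in
    the C-ring window above a density quantile, excluding the cap at the
    top of the wall; fit an ellipse (intensity-weighted second moments by
    default); the tilt is the angle between the major axis and the rotation
    axis, averaged over the two walls.
    """
    cfg = config or TiltConfig()
    vs = vol.voxel_size_nm
    nz, ny, nx = vol.shape
    ox, oy, oz = vol.origin_voxel
    # n-fold symmetrization and cross-section extraction fused into one
    # interpolation pass: the cross-section of the n-symmetrized map equals
    # the average of axial planes sampled at the n azimuths.  The plane is
    # averaged over a thin slab and resampled at half-voxel steps so the thin
    # wall band is represented by enough samples.
    x_nm = np.arange(-(ox - 1) * vs, (nx - ox - 1) * vs, vs / 2.0)
    z_nm = np.arange(-(oz - 1) * vs, (nz - oz - 1) * vs, vs / 2.0)
    y_off = np.arange(-cfg.slab_halfwidth_voxels, cfg.slab_halfwidth_voxels + 1, dtype=float)
    xx, yy, zz = np.meshgrid(x_nm / vs, y_off, z_nm / vs, indexing="ij")
    data = vol.data.astype(np.float64)
    cross = np.zeros(xx.shape[::2])
    for k in range(cfg.n_sym):
        th = 2.0 * np.pi * k / cfg.n_sym
        xr = xx * np.cos(th) - yy * np.sin(th) + ox
        yr = xx * np.sin(th) + yy * np.cos(th) + oy
        cross += ndimage.map_coordinates(
            data, [zz + oz, yr, xr], order=1, mode="constant", cval=0.0, prefilter=False
        ).mean(axis=1)
    cross /= cfg.n_sym  # (x, z)

    fit_fn = {"moments": _ellipse_moments, "conic": _ellipse_conic}.get(cfg.method)
    if fit_fn is None:
        raise ValidationError(f"unknown ellipse-fit method '{cfg.method}'")
    fits = {}
    for side, name in ((+1, "right"), (-1, "left")):
        pts, w = _wall_points(cross, x_nm, z_nm, cfg, side)
        fits[name] = fit_fn(pts, w)
    t_r = fits["right"].major_axis_angle_deg
    t_l = fits["left"].major_axis_angle_deg
    return TiltResult(
        tilt_deg=0.5 * (t_r + t_l),
        side="mean",
        fit_left=fits["left"],
        fit_right=fits["right"],
        quality_flag=abs(t_r - t_l) > 2.0,
    )


def unroll_map(vol: Volume, r_range, z_range, angular_samples: int) -> np.ndarray:
    """Resample onto a cylindrical ``(theta, z, r)`` grid; theta covers [0, 360).

    ``r_range``/``z_range`` are in nm around the rotation axis; radial and
    axial steps are half a voxel.  The radial range must exclude 0 (the
    cylindrical Jacobian degenerates on the axis).
    """
    r_lo, r_hi = r_range
    if r_lo <= 0:
        raise ValidationError("r_range must exclude 0")
    z_lo, z_hi = z_range
    vs = vol.voxel_size_nm
    ox, oy, oz = vol.origin_voxel
    radii = np.arange(r_lo, r_hi + 1e-9, vs / 2.0)
    zs = np.arange(z_lo, z_hi + 1e-9, vs / 2.0)
    theta = np.linspace(0.0, 2.0 * np.pi, angular_samples, endpoint=False)
    tt, zz, rr = np.meshgrid(theta, zs, radii, indexing="ij")
    x = rr * np.cos(tt) / vs + ox
    y = rr * np.sin(tt) / vs + oy
    z = zz / vs + oz
    nzv, nyv, nxv = vol.shape
    if (x.min() < 0 or y.min() < 0 or z.min() < 0
            or x.max() > nxv - 1 or y.max() > nyv - 1 or z.max() > nzv - 1):
        raise ValidationError("requested cylindrical range extends outside the volume")
    return ndimage.map_coordinates(
        vol.data.astype(np.float64), [z, y, x], order=1, mode="constant", cval=0.0,
        prefilter=False,
    )
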