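"""Stator-site extraction, focused alignment, classification, and occupancy.

The 16 putative stator positions of each motor are brought into one
canonical frame (site at ``(+site_radius, 0, site_z)``), scored by their
mean density inside a spherical stator mask relative to an off-site control
position, and classified occupied / empty / ambiguous with a two-component
Gaussian mixture on the scores.  The occupancy statistic divides the
occupied-site count by the *total* site count (ambiguous sites stay in the
denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .averaging import SearchSpec
from .errors import ValidationError
from .volume_io import Volume, euler_to_matrix

__all__ = [
    "SiteRecord",
    "OccupancyEstimate",
    "extract_site_subvolumes",
    "focused_align_sites",
    "site_scores",
    "classify_scores",
    "classify_sites",
    "estimate_occupancy",
]

#: Default geometry of the canonical stator site (nm).
SITE_RADIUS_NM = 40.0
SITE_Z_NM = -1.0
STATOR_MASK_RADIUS_NM = 6.0


@dataclass
class SiteRecord:
    motor_id: str
    site_index: int
    subvolume: Volume
    masked_mean: float = float("nan")
    class_label: str = "unset"


@dataclass
class OccupancyEstimate:
    n_occupied: int
    n_empty: int
    n_ambiguous: int
    occupancy: float  # occupied / total, ambiguous in the denominator
    mean_stators_per_motor: float  # occupancy * n_sites


def extract_site_subvolumes(
    motor: Volume,
    pose=((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
    n_sites: int = 16,
    site_radius_nm: float = SITE_RADIUS_NM,
    site_z_nm: float = SITE_Z_NM,
    box_nm: float = 20.0,
) -> list[Volume]:
    """Crop the ``n_sites`` stator-site subvolumes of one motor.

    ``pose = (euler_deg, shift_voxels)`` is the alignment of the motor into
    the canonical frame.  Site ``k`` is brought to the canonical position
    by an extra ``-k * 360/n_sites`` rotation about z, and a cube of edge
    ``box_nm`` centered on ``(site_radius_nm, 0, site_z_nm)`` is resampled
    in a single interpolation pass.  All subvolumes share that canonical
    frame.
    """
    vs = motor.voxel_size_nm
    b = int(round(box_nm / vs))
    if b < 8:
        raise ValidationError(f"site box of {box_nm} nm is under 8 voxels at {vs} nm/voxel")
    euler, shift = pose
    r_pose = euler_to_matrix(euler)
    t = np.asarray(shift, dtype=float)
    c = np.asarray(motor.origin_voxel, dtype=float)
    # canonical -> motor voxel coordinates (inverse of the alignment pose)
    r_inv = r_pose.T

    half = (b - 1) / 2.0
    ax = (np.arange(b) - half) * 1.0  # voxel offsets within the site box
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    center_canon = np.array([site_radius_nm, 0.0, site_z_nm]) / vs
    nzv, nyv, nxv = motor.shape
    data64 = motor.data.astype(np.float64)

    out = []
    for k in range(n_sites):
        th = 2.0 * math.pi * k / n_sites
        rot_k = np.array(
            [[math.cos(th), -math.sin(th), 0.0], [math.sin(th), math.cos(th), 0.0], [0.0, 0.0, 1.0]]
        )
        # canonical-frame sample points for site k, in voxels about the origin
        pts = np.stack([xx, yy, zz], axis=0) + center_canon[:, None, None, None]
        pts = np.tensordot(rot_k, pts, axes=(1, 0))  # +k rotation back to site k
        pts = np.tensordot(r_inv, pts - (t + 0.0)[:, None, None, None] / 1.0, axes=(1, 0))
        pts = pts + c[:, None, None, None]
        x, y, z = pts
        if (x.min() < 0 or y.min() < 0 or z.min() < 0
                or x.max() > nxv - 1 or y.max() > nyv - 1 or z.max() > nzv - 1):
            raise ValidationError(f"site {k} crop extends outside the motor volume")
        sub = ndimage.map_coordinates(data64, [z, y, x], order=1, mode="constant", cval=0.0,
                                      prefilter=False)
        out.append(Volume(sub.astype(np.float32), vs, origin_voxel=(half, half, half)))
    return out


def _spherical_mask(box_shape, center_voxel, radius_voxels) -> np.ndarray:
    nz, ny, nx = box_shape
    cz, cy, cx = center_voxel
    z = (np.arange(nz) - cz)[:, None, None]
    y = (np.arange(ny) - cy)[None, :, None]
    x = (np.arange(nx) - cx)[None, None, :]
    return (x * x + y * y + z * z) <= radius_voxels**2


def default_stator_mask(box_shape, voxel_size_nm, radius_nm=STATOR_MASK_RADIUS_NM) -> Volume:
    """Sphere of ``radius_nm`` at the canonical stator position (box center)."""
    nz, ny, nx = box_shape
    center = ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0)
    mask = _spherical_mask(box_shape, center, radius_nm / voxel_size_nm)
    return Volume(mask.astype(np.float32), voxel_size_nm,
                  origin_voxel=(center[2], center[1], center[0]))


def rotate_site_about_rod(site: Volume, angle_deg: float,
                          site_radius_nm: float = SITE_RADIUS_NM) -> Volume:
    """Rotate a canonical-frame site subvolume about the motor rod axis.

    The rod (z) axis sits ``site_radius_nm`` inward of the site-box center,
    so a small rod rotation moves the site mostly tangentially.
    """
    from .volume_io import apply_pose

    ox, oy, oz = site.origin_voxel
    rod_origin = (ox - site_radius_nm / site.voxel_size_nm, oy, oz)
    shifted = Volume(site.data, site.voxel_size_nm, origin_voxel=rod_origin)
    out = apply_pose(shifted, (angle_deg, 0.0, 0.0), (0.0, 0.0, 0.0))
    return Volume(out.data, site.voxel_size_nm, origin_voxel=site.origin_voxel)


def focused_align_sites(sites, reference: Volume, search: SearchSpec,
                        site_radius_nm: float = SITE_RADIUS_NM):
    """Refine each site's rotation about the motor rod under the focused cap.

    The angular search about the rod axis is restricted to
    ``< search.max_axis_rot_deg`` (which must be <= 2 degrees, the
    focused-classification restriction); a pose at the search boundary or
    with a poor score is flagged.  Returns a list of
    ``((euler, shift), score, flagged)`` where the Euler triple is the rod
    rotation to apply to the site.
    """
    if search.max_axis_rot_deg > 2.0:
        raise ValidationError(
            f"focused alignment requires max_axis_rot_deg <= 2, got {search.max_axis_rot_deg}"
        )
    step = search.angular_grid_deg
    n = int(np.floor((search.max_axis_rot_deg - 1e-9) / step))
    angles = np.arange(-n, n + 1) * step  # strictly inside the +/- cap
    ref = reference.data.astype(np.float64)
    if search.mask is not None:
        ref = ref * search.mask.data
    ref = ref - ref.mean()
    ref_norm = np.linalg.norm(ref)
    results = []
    for site in sites:
        best = None
        for ang in angles:
            rot = rotate_site_about_rod(site, float(ang), site_radius_nm).data.astype(np.float64)
            if search.mask is not None:
                rot = rot * search.mask.data
            rot = rot - rot.mean()
            den = ref_norm * np.linalg.norm(rot)
            sc = float(np.sum(ref * rot) / den) if den > 0 else -np.inf
            if best is None or sc > best[1]:
                best = (float(ang), sc)
        ang, sc = best
        flagged = (abs(ang) >= angles.max() - 1e-9 and len(angles) > 1) or sc < 0.5
        results.append((((ang, 0.0, 0.0), (0.0, 0.0, 0.0)), sc, flagged))
    return results


def site_scores(sites, stator_mask: Volume | None = None, background_correct: bool = True):
    """Mean density of each site inside the stator mask.

    With ``background_correct`` the mean over the same mask displaced to an
    off-site control position (half a site spacing away tangentially) is
    subtracted, which removes membrane and offset contributions and gives
    the scores an absolute zero for stator-free sites.
    """
    sites = list(sites)
    if len(sites) == 0:
        raise ValidationError("no sites given")
    vs = sites[0].voxel_size_nm
    shape = sites[0].shape
    if stator_mask is None:
        stator_mask = default_stator_mask(shape, vs)
    m = stator_mask.data > 0.5
    if not m.any():
        raise ValidationError("empty stator mask")
    scores = np.array([float(s.data[m].mean()) for s in sites])
    if background_correct:
        # control mask: same z, same radius from the axis, rotated by half a
        # site spacing (11.25 deg at 40 nm radius ~ 7.8 nm away tangentially)
        dy = SITE_RADIUS_NM * math.tan(math.radians(11.25)) / vs
        ctrl = np.roll(m, int(round(dy)), axis=1)
        ctrl_scores = np.array([float(s.data[ctrl].mean()) for s in sites])
        scores = scores - ctrl_scores
    return scores


def wedge_attenuation_calibration(strain, wedge, box_voxels: int = 96,
                                  voxel_size_nm: float = 1.25):
    """Per-site score anchors from noiseless wedge-filtered reference phantoms.

    The missing wedge smears neighboring densities anisotropically, so the
    masked-mean score of an occupied site depends on its azimuth relative
    to the tilt axis.  This computes the expected score of every site on a
    fully occupied (``a_k``) and a fully empty (``b_k``) wedge-filtered
    phantom of the same geometry; ``(score - b_k) / (a_k - b_k)`` then puts
    all sites on one absolute scale (0 = empty, 1 = occupied).
    """
    from .phantom_sim import apply_missing_wedge, build_motor_phantom

    n = strain.n_collar
    a_vol = apply_missing_wedge(
        build_motor_phantom(strain, np.ones(n, bool), box_voxels, voxel_size_nm), wedge
    )
    b_vol = apply_missing_wedge(
        build_motor_phantom(strain, np.zeros(n, bool), box_voxels, voxel_size_nm), wedge
    )
    a = site_scores(extract_site_subvolumes(a_vol, n_sites=n))
    b = site_scores(extract_site_subvolumes(b_vol, n_sites=n))
    if np.any(a - b <= 0):
        raise ValidationError("degenerate calibration: occupied reference not above empty")
    return a, b


def classify_scores(scores, seed: int = 0, abs_threshold: float | None = None,
                    posterior: float = 0.8):
    """Label scores occupied/empty/ambiguous with a 1D two-component mixture.

    The mixture is initialized at the 10th/90th score percentiles (seeded).
    A site is ``occupied`` when its posterior for the high-mean component is
    at least ``posterior``, ``empty`` when the low-mean posterior is, and
    ``ambiguous`` otherwise.  ``abs_threshold`` (same units as the scores)
    is the minimum component mean that counts as genuine stator density.
    When the fitted mixture is degenerate with respect to that scale (both
    component means on the same side of it, as for fully empty or fully
    occupied ensembles where there is no second class to separate), sites
    are labeled directly by the absolute threshold.
    """
    from sklearn.mixture import GaussianMixture

    s = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise ValidationError("need at least two sites to classify")
    if np.ptp(s) == 0:
        return ["ambiguous"] * len(s)
    q10, q90 = np.quantile(s, [0.1, 0.9])
    gmm = GaussianMixture(
        n_components=2,
        means_init=np.array([[q10], [q90]]),
        n_init=1,
        random_state=seed,
        reg_covar=1e-10 * max(s.var(), 1e-30),
    )
    gmm.fit(s.reshape(-1, 1))
    means = gmm.means_.ravel()
    lo, hi = int(np.argmin(means)), int(np.argmax(means))
    if abs_threshold is not None and (means[hi] < abs_threshold or means[lo] >= abs_threshold):
        return ["occupied" if v >= abs_threshold else "empty" for v in s]
    resp = gmm.predict_proba(s.reshape(-1, 1))
    labels = []
    for p in resp:
        if p[hi] >= posterior:
            labels.append("occupied")
        elif p[lo] >= posterior:
            labels.append("empty")
        else:
            labels.append("ambiguous")
    return labels


def classify_sites(sites, stator_mask: Volume | None = None, seed: int = 0,
                   calibration=None):
    """Classify site subvolumes occupied/empty/ambiguous.

    Scores are background-corrected masked means (see :func:`site_scores`).
    With ``calibration = (a_k, b_k)`` (see
    :func:`wedge_attenuation_calibration`) scores are normalized to the
    absolute 0/1 scale first and the stator-density floor sits at its
    midpoint 0.5; without it the floor is five times the robust site-to-site
    noise scale estimated from the lower half of the score distribution.
    """
    sites = list(sites)
    if len(sites) < 2:
        raise ValidationError("need at least two sites")
    scores = site_scores(sites, stator_mask=stator_mask)
    if calibration is not None:
        a, b = calibration
        n = len(a)
        idx = np.arange(len(scores)) % n
        scores = (scores - b[idx]) / (a[idx] - b[idx])
        abs_threshold = 0.5
    else:
        # robust noise scale from the spread of the lower half of the scores
        med = np.median(scores)
        lower = scores[scores <= med]
        noise = 1.4826 * np.median(np.abs(lower - np.median(lower))) if len(lower) > 2 else 0.0
        abs_threshold = 5.0 * max(noise, 1e-12)
    return classify_scores(scores, seed=seed, abs_threshold=abs_threshold)


def estimate_occupancy(labels, n_sites_per_motor: int = 16) -> OccupancyEstimate:
    """Occupancy statistic: occupied sites / all sites (ambiguous included
    in the denominator)."""
    labels = list(labels)
    if len(labels) == 0:
        raise ValidationError("no labels given")
    bad = set(labels) - {"occupied", "empty", "ambiguous"}
    if bad:
        raise ValidationError(f"unknown labels: {sorted(bad)}")
    n_occ = labels.count("occupied")
    n_emp = labels.count("empty")
    n_amb = labels.count("ambiguous")
    occ = n_occ / len(labels)
    return OccupancyEstimate(
        n_occupied=n_occ,
        n_empty=n_emp,
        n_ambiguous=n_amb,
        occupancy=occ,
        mean_stators_per_motor=occ * n_sites_per_motor,
    )
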