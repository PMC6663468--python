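"""Volumes, particle tables, and the coordinate/pose conventions used everywhere.

Conventions (fixed here, obeyed by every other module)
------------------------------------------------------
* Right-handed coordinate frame; ``z`` is the motor rotation axis pointing
  from the C-ring toward the hook; the origin sits at the MS-ring center.
* ``Volume.data`` is indexed ``[z, y, x]`` (NumPy / scikit-image order);
  voxel indexing is 0-based with voxel centers at integer coordinates.
* Euler angles are **ZYZ intrinsic**, in degrees, normalized to
  ``[-180, 180)``.  A pose ``(euler, shift)`` acts *rotate-then-shift*:

      T(x) = R_zyz(euler) @ (x - c) + c + t

  where ``c`` is the rotation-axis center (``Volume.origin_voxel``) and the
  shift ``t`` is in voxels.  Applying a pose to a volume resamples it with
  trilinear interpolation.
* Particle metadata travels as a tab-separated table with STAR-like column
  semantics (columns ``particle_id, motor_id, site_index, phi, theta, psi,
  dx, dy, dz, score, class_label``); unknown columns round-trip verbatim.

Volumes are stored on disk as MRC2014 maps (via :mod:`gemmi`); header cell
dimensions are in Angstrom, so voxel sizes convert by a factor of 10 to the
nanometers used in memory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import FormatError, ValidationError

#: Canonical particle-table columns, in on-disk order.
PARTICLE_COLUMNS = (
    "particle_id",
    "motor_id",
    "site_index",
    "phi",
    "theta",
    "psi",
    "dx",
    "dy",
    "dz",
    "score",
    "class_label",
)

CLASS_LABELS = ("occupied", "empty", "ambiguous", "unset")


def normalize_euler(angles_deg):
    """Wrap Euler angles (degrees) into ``[-180, 180)``."""
    return (np.asarray(angles_deg, dtype=float) + 180.0) % 360.0 - 180.0


def euler_to_matrix(euler_deg) -> np.ndarray:
    """3x3 rotation matrix (acting on ``(x, y, z)`` vectors) for ZYZ-intrinsic angles."""
    return Rotation.from_euler("ZYZ", np.asarray(euler_deg, dtype=float), degrees=True).as_matrix()


def matrix_to_euler(mat: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_to_matrix`; angles normalized to ``[-180, 180)``."""
    return normalize_euler(Rotation.from_matrix(mat).as_euler("ZYZ", degrees=True))


def compose_pose(euler1, shift1, euler2, shift2):
    """Pose equivalent to applying pose 1 then pose 2 (both rotate-then-shift)."""
    r1, r2 = euler_to_matrix(euler1), euler_to_matrix(euler2)
    t1 = np.asarray(shift1, dtype=float)
    t2 = np.asarray(shift2, dtype=float)
    return matrix_to_euler(r2 @ r1), r2 @ t1 + t2


def invert_pose(euler_deg, shift_voxels):
    """Pose undoing ``(euler_deg, shift_voxels)``."""
    r = euler_to_matrix(euler_deg)
    t = np.asarray(shift_voxels, dtype=float)
    return matrix_to_euler(r.T), -r.T @ t


@dataclass
class Volume:
    """A 3D density grid with a physical voxel size.

    Parameters
    ----------
    data:
        3D float array, indexed ``[z, y, x]``.
    voxel_size_nm:
        Edge length of one (cubic) voxel, in nanometers.
    origin_voxel:
        ``(x, y, z)`` voxel coordinates of the rotation-axis center.
        Defaults to the box center ``shape // 2``.
    """

    data: np.ndarray
    voxel_size_nm: float
    origin_voxel: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.origin_voxel is None:
            nz, ny, nx = self.data.shape if self.data.ndim == 3 else (0, 0, 0)
            self.origin_voxel = np.array([nx // 2, ny // 2, nz // 2], dtype=float)
        else:
            self.origin_voxel = np.asarray(self.origin_voxel, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3D, got ndim={self.data.ndim}")
        if any(n < 8 for n in self.data.shape):
            raise ValidationError(f"grid dimensions must be >= 8, got {self.data.shape}")
        if not np.isfinite(self.voxel_size_nm) or self.voxel_size_nm <= 0:
            raise ValidationError(f"voxel_size_nm must be positive, got {self.voxel_size_nm}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite values")

    @property
    def shape(self):
        return self.data.shape

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.voxel_size_nm, self.origin_voxel.copy())

    def coordinate_grids_nm(self):
        """Physical ``(x, y, z)`` coordinate grids (nm, relative to the origin voxel),
        each shaped like ``data``."""
        nz, ny, nx = self.data.shape
        ox, oy, oz = self.origin_voxel
        z = (np.arange(nz) - oz)[:, None, None] * self.voxel_size_nm
        y = (np.arange(ny) - oy)[None, :, None] * self.voxel_size_nm
        x = (np.arange(nx) - ox)[None, None, :] * self.voxel_size_nm
        zz, yy, xx = np.broadcast_arrays(z, y, x)
        return xx, yy, zz


def apply_pose(vol: Volume, euler_deg, shift_voxels, inverse: bool = False) -> Volume:
    """Resample ``vol`` under the rigid pose (rotate-then-shift about the origin voxel).

    With ``inverse=True`` the inverse transform is applied, so
    ``apply_pose(apply_pose(v, e, s), e, s, inverse=True)`` recovers ``v``
    up to interpolation error.
    """
    r = euler_to_matrix(euler_deg)
    t = np.asarray(shift_voxels, dtype=float)
    c = np.asarray(vol.origin_voxel, dtype=float)
    if inverse:
        # sample input at T(y) = R(y - c) + c + t
        m_xyz, off_xyz = r, c + t - r @ c
    else:
        # sample input at T^-1(y) = R^T (y - c - t) + c
        m_xyz, off_xyz = r.T, c - r.T @ (c + t)
    flip = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
    m_zyx = flip @ m_xyz @ flip
    off_zyx = flip @ off_xyz
    out = ndimage.affine_transform(
        vol.data.astype(np.float32, copy=False),
        m_zyx,
        offset=off_zyx,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return vol.copy_with(out)


def rotate_about_z(vol: Volume, angle_deg: float) -> Volume:
    """Rotate about the motor (z) axis through the origin voxel."""
    return apply_pose(vol, (angle_deg, 0.0, 0.0), (0.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# MRC2014 I/O (gemmi backend)
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume:
    """Read an MRC2014 / CCP4 map into a :class:`Volume`.

    The voxel size is taken from the header cell (Angstrom) and converted to
    nanometers.  Only near-isotropic voxel sizes are supported.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"not a readable MRC2014 map: {path}: {exc}") from exc
    data = np.array(m.grid, copy=True).astype(np.float32)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D map, got ndim={data.ndim}")
    spacing = np.asarray(m.grid.spacing, dtype=float)  # Angstrom
    if not np.all(spacing > 0):
        raise FormatError(f"non-positive voxel size in header: {spacing}")
    if np.ptp(spacing) > 1e-3 * spacing.mean():
        raise FormatError(f"anisotropic voxel size unsupported: {spacing} A")
    try:
        return Volume(data, voxel_size_nm=float(spacing.mean()) / 10.0)
    except ValidationError as exc:
        raise FormatError(f"invalid map contents: {exc}") from exc


def write_volume(vol: Volume, path) -> None:
    """Write a :class:`Volume` as a 32-bit float MRC2014 map (bit-exact round-trip)."""
    vol.validate()
    grid = gemmi.FloatGrid(np.ascontiguousarray(vol.data, dtype=np.float32))
    a = vol.voxel_size_nm * 10.0  # nm -> Angstrom
    grid.unit_cell = gemmi.UnitCell(grid.nu * a, grid.nv * a, grid.nw * a, 90, 90, 90)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write map to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Particle tables
# ---------------------------------------------------------------------------

class ParticleTable:
    """Per-subtomogram pose / provenance / classification records.

    Thin validated wrapper around a :class:`pandas.DataFrame`.  ``phi, theta,
    psi`` are the ZYZ-intrinsic Euler angles (degrees) and ``dx, dy, dz`` the
    shift in voxels of the pose that maps the subtomogram into the canonical
    motor frame.  ``site_index`` is the stator site (0-15) for site-level
    records and empty for whole-motor records.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in PARTICLE_COLUMNS:
            if col not in df.columns:
                if col == "class_label":
                    df[col] = "unset"
                elif col in ("particle_id", "motor_id"):
                    raise ValidationError(f"missing required column '{col}'")
                else:
                    df[col] = np.nan
        df["particle_id"] = df["particle_id"].astype(str)
        df["motor_id"] = df["motor_id"].astype(str)
        for col in ("phi", "theta", "psi"):
            df[col] = normalize_euler(df[col].astype(float))
        df["class_label"] = df["class_label"].fillna("unset").astype(str)
        self._df = df
        self.validate()

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParticleTable):
            return NotImplemented
        a = self._df.reset_index(drop=True)
        b = other._df.reset_index(drop=True)
        if set(a.columns) != set(b.columns) or len(a) != len(b):
            return False
        b = b[a.columns]
        for col in a.columns:
            if a[col].dtype.kind == "f" or b[col].dtype.kind == "f":
                av = a[col].astype(float).to_numpy()
                bv = b[col].astype(float).to_numpy()
                both_nan = np.isnan(av) & np.isnan(bv)
                if not np.all(both_nan | np.isclose(av, bv, rtol=1e-8, atol=1e-9)):
                    return False
            elif not a[col].astype(str).equals(b[col].astype(str)):
                return False
        return True

    def validate(self) -> None:
        df = self._df
        if df["particle_id"].duplicated().any():
            dupes = df.loc[df["particle_id"].duplicated(), "particle_id"].tolist()
            raise ValidationError(f"duplicate particle_id values: {dupes}")
        site = pd.to_numeric(df["site_index"], errors="coerce")
        present = site.notna()
        if present.any():
            vals = site[present]
            if ((vals < 0) | (vals > 15) | (vals != vals.round())).any():
                raise ValidationError("site_index must be an integer in [0, 15] when present")
        bad = ~df["class_label"].isin(CLASS_LABELS)
        if bad.any():
            raise ValidationError(
                f"unknown class_label values: {sorted(df.loc[bad, 'class_label'].unique())}"
            )


def read_particles(path) -> ParticleTable:
    """Read a tab-separated particle table (header line required)."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype={"particle_id": str, "motor_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise FormatError(f"not a readable particle TSV: {path}: {exc}") from exc
    return ParticleTable(df)


def write_particles(table: ParticleTable, path) -> None:
    """Write a particle table as TSV; canonical columns first, extras verbatim."""
    df = table.df
    extras = [c for c in df.columns if c not in PARTICLE_COLUMNS]
    ordered = list(PARTICLE_COLUMNS) + extras
    df[ordered].to_csv(path, sep="\t", index=False, float_format="%.10g")
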