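"""Analytic missing-wedge geometry in Fourier space.

Single-axis tomographic tilting over ``[tilt_min, tilt_max]`` samples, for
every spatial frequency, only the directions whose inclination out of the
untilted specimen plane lies inside the tilt range.  For tilt axis ``a`` and
beam direction ``b = z`` the inclination of a frequency vector ``k`` is

    psi = atan2(k . b, k . c),   c = a x b,

wrapped into ``[-90, 90)`` (Hermitian symmetry: ``k`` and ``-k`` wrap to the
same inclination).  A voxel is covered iff ``tilt_min <= psi <= tilt_max``.
The tilt-axis line (including DC) is sampled by every image and is always
covered.

Masks are evaluated analytically on the (optionally rotated) frequency grid,
so a rotated mask is exactly binary — coverage counts stay integers.
"""

from __future__ import annotations

import numpy as np

BEAM_AXIS = np.array([0.0, 0.0, 1.0])


def wedge_mask_array(
    tilt_min_deg: float,
    tilt_max_deg: float,
    shape,
    tilt_axis=(0.0, 1.0, 0.0),
    rot_xyz: np.ndarray | None = None,
    shifted: bool = False,
) -> np.ndarray:
    """Boolean coverage mask on the FFT frequency grid of ``shape`` (z, y, x).

    ``rot_xyz`` (3x3, acting on ``(x, y, z)``) evaluates the mask for a volume
    that has been rotated by that matrix in real space: frequency ``k`` of the
    rotated volume came from frequency ``R^T k`` of the original, so the mask
    is evaluated at ``R^T k``.  With ``shifted=True`` the grid is
    ``fftshift``-ordered instead of the natural FFT layout.
    """
    nz, ny, nx = shape
    freq = np.fft.fftshift if shifted else (lambda v: v)
    kz = freq(np.fft.fftfreq(nz))[:, None, None]
    ky = freq(np.fft.fftfreq(ny))[None, :, None]
    kx = freq(np.fft.fftfreq(nx))[None, None, :]

    a = np.asarray(tilt_axis, dtype=float)
    a = a / np.linalg.norm(a)
    if abs(np.dot(a, BEAM_AXIS)) > 1.0 - 1e-9:
        raise ValueError("tilt axis must not be parallel to the beam (z) axis")
    c = np.cross(a, BEAM_AXIS)
    c = c / np.linalg.norm(c)
    b = BEAM_AXIS
    if rot_xyz is not None:
        # evaluate at R^T k  <=>  project k onto rotated basis vectors R b, R c
        r = np.asarray(rot_xyz, dtype=float)
        b, c = r @ b, r @ c

    k_b = kx * b[0] + ky * b[1] + kz * b[2]
    k_c = kx * c[0] + ky * c[1] + kz * c[2]
    psi = np.degrees(np.arctan2(k_b, k_c))
    psi = (psi + 90.0) % 180.0 - 90.0
    mask = (psi >= tilt_min_deg) & (psi <= tilt_max_deg)
    # the tilt-axis line (k_b = k_c = 0) appears in every tilt image
    mask |= (np.abs(k_b) < 1e-12) & (np.abs(k_c) < 1e-12)
    if not shifted:
        # Nyquist bins on even axes alias +0.5 and -0.5 cycles/voxel into one
        # index; OR with the conjugate flip keeps the mask exactly Hermitian
        conj = np.roll(mask[::-1, ::-1, ::-1], (1, 1, 1), axis=(0, 1, 2))
        mask |= conj
    return mask
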