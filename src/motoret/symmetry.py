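"""Rotational-symmetry detection and n-fold symmetrization about the motor axis.

Symmetry order is read off the angular power spectrum of a cylindrical
shell: the density is resampled onto a (theta, z, r) grid around the
rotation axis, averaged over z and r, and Fourier-analyzed in theta.  A
ring of N identical subunits excites harmonics N, 2N, ... and never the
divisors of N, so the fundamental is scored as the order's power plus half
the power of its first harmonic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volume_io import Volume, rotate_about_z


@dataclass
class SymmetrySpectrum:
    """Normalized angular-harmonic power per integer order over one shell."""

    orders: np.ndarray  # strictly increasing integers
    power: np.ndarray  # normalized to the total non-DC power (sums to <= 1)
    shell: tuple  # (r_min_nm, r_max_nm, z_min_nm, z_max_nm)
    dc_power: float = 0.0  # raw |c_0|^2, the absolute significance reference
    total_power: float = 0.0  # raw total non-DC power

    def power_at(self, order: int) -> float:
        idx = np.searchsorted(self.orders, order)
        if idx >= len(self.orders) or self.orders[idx] != order:
            raise ValidationError(f"order {order} not in spectrum")
        return float(self.power[idx])


def _cylindrical_profile(vol: Volume, shell, n_theta: int) -> np.ndarray:
    """Mean density as a function of theta over the given (r, z) shell."""
    r_min, r_max, z_min, z_max = shell
    vs = vol.voxel_size_nm
    ox, oy, oz = vol.origin_voxel
    radii = np.arange(r_min, r_max + 1e-9, vs / 2.0)
    zs = np.arange(z_min, z_max + 1e-9, vs / 2.0)
    if len(radii) == 0 or len(zs) == 0:
        raise ValidationError(f"empty shell {shell}")
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    tt, zz, rr = np.meshgrid(theta, zs, radii, indexing="ij")
    x = rr * np.cos(tt) / vs + ox
    y = rr * np.sin(tt) / vs + oy
    z = zz / vs + oz
    nzv, nyv, nxv = vol.shape
    if (x.min() < 0 or y.min() < 0 or z.min() < 0
            or x.max() > nxv - 1 or y.max() > nyv - 1 or z.max() > nzv - 1):
        raise ValidationError("shell extends outside the volume")
    samples = ndimage.map_coordinates(
        vol.data.astype(np.float64), [z, y, x], order=1, mode="constant", cval=0.0,
        prefilter=False,
    )
    return samples.mean(axis=(1, 2))


def angular_power_spectrum(
    vol: Volume, shell, n_max: int, n_min: int = 1, angular_oversample: int = 4
) -> SymmetrySpectrum:
    """Normalized angular-harmonic power of a cylindrical shell.

    Parameters
    ----------
    shell:
        ``(r_min_nm, r_max_nm, z_min_nm, z_max_nm)`` around the rotation axis.
    n_max, n_min:
        Range of integer orders to report; the angular grid uses
        ``angular_oversample * n_max`` samples (Nyquist margin).
    """
    if n_max < max(n_min, 1):
        raise ValidationError("n_max must be >= max(n_min, 1)")
    n_theta = angular_oversample * n_max
    profile = _cylindrical_profile(vol, shell, n_theta)
    coeff = np.fft.rfft(profile)
    power_all = np.abs(coeff) ** 2
    total = power_all[1:].sum()
    orders = np.arange(max(n_min, 1), n_max + 1)
    if total <= 0:
        power = np.zeros(len(orders))
    else:
        power = power_all[orders] / total
    return SymmetrySpectrum(orders=orders, power=power, shell=tuple(shell),
                            dc_power=float(power_all[0]), total_power=float(total))


#: minimum raw harmonic power, relative to DC, for a peak to count as real
#: angular structure rather than interpolation residue
DC_SIGNIFICANCE = 1e-5


def detect_symmetry_order(spectrum: SymmetrySpectrum) -> int:
    """Fundamental symmetry order, or 0 if no order stands out.

    Scores each candidate ``m`` as ``power(m) + power(2m)/2`` (a ring of N
    blobs puts power at N and its harmonics, never at divisors of N), and
    declares the best candidate only if its own power exceeds three times
    the median power across candidates and, when the DC power is known, a
    small fraction of it (a continuous ring has no angular power beyond
    numerical residue).
    """
    if len(spectrum.orders) == 0:
        raise ValidationError("empty spectrum")
    orders = spectrum.orders
    power = spectrum.power
    lookup = {int(m): float(p) for m, p in zip(orders, power)}
    scores = np.array([p + 0.5 * lookup.get(int(2 * m), 0.0) for m, p in zip(orders, power)])
    best = int(np.argmax(scores))
    med = float(np.median(power))
    if not (power[best] > 3.0 * med and power[best] > 0):
        return 0
    if spectrum.dc_power > 0:
        raw_peak = power[best] * spectrum.total_power
        if raw_peak < DC_SIGNIFICANCE * spectrum.dc_power:
            return 0
    return int(orders[best])


def symmetrize(vol: Volume, n: int) -> Volume:
    """Average the volume over rotations by ``k * 360/n`` about the z axis."""
    if n < 1:
        raise ValidationError(f"symmetry order must be >= 1, got {n}")
    if n == 1:
        return vol.copy_with(vol.data.copy())
    acc = np.zeros_like(vol.data, dtype=np.float64)
    for k in range(n):
        acc += rotate_about_z(vol, 360.0 * k / n).data
    return vol.copy_with((acc / n).astype(vol.data.dtype))
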