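"""Shared discrete-Fourier conventions and angular-spectrum primitives.

Conventions (used everywhere in the package):

* real-space arrays are stored with the coordinate origin at index ``n // 2``
  along every axis (``GridSpec.coords``);
* spectra are stored in unshifted (``numpy.fft``) frequency order;
* the forward transform approximates the continuous integral
  ``a~(u) = int a(r) exp(-i 2 pi u . r) dr`` (``ft``), the inverse carries the
  reciprocal measure (``ift``).

The axial response of the scalar outgoing-wave propagator over the finite,
periodically-sampled z window is the Dirichlet kernel ``dirichlet_kernel``;
evaluating it at analytically shifted arguments keeps the transfer-function
assembly consistent with the FFT-based scattering simulator.
"""

from __future__ import annotations

import numpy as np

from .tensor_core import GridSpec

__all__ = [
    "ft",
    "ift",
    "ft2",
    "ift2",
    "dirichlet_kernel",
    "propagation_eta",
    "transverse_green",
    "incident_polarization",
]


def ft(a: np.ndarray, grid: GridSpec, axes=(-3, -2, -1)) -> np.ndarray:
    """Continuous-convention 3D Fourier transform of a centered volume."""
    d = grid.voxel_volume
    return np.fft.fftn(np.fft.ifftshift(a, axes=axes), axes=axes) * d


def ift(A: np.ndarray, grid: GridSpec, axes=(-3, -2, -1)) -> np.ndarray:
    """Inverse of :func:`ft`."""
    d = grid.voxel_volume
    return np.fft.fftshift(np.fft.ifftn(A, axes=axes), axes=axes) / d


def ft2(a: np.ndarray, grid: GridSpec, axes=(-2, -1)) -> np.ndarray:
    dy, dx = grid.spacing[1], grid.spacing[2]
    return np.fft.fftn(np.fft.ifftshift(a, axes=axes), axes=axes) * (dy * dx)


def ift2(A: np.ndarray, grid: GridSpec, axes=(-2, -1)) -> np.ndarray:
    dy, dx = grid.spacing[1], grid.spacing[2]
    return np.fft.fftshift(np.fft.ifftn(A, axes=axes), axes=axes) / (dy * dx)


def dirichlet_kernel(c: np.ndarray, nz: int, dz: float) -> np.ndarray:
    """``dz * sum_j exp(i 2 pi c z_j)`` over the centered z grid.

    This is the finite-window axial spectrum of a unit plane wave
    ``exp(i 2 pi c z)``; it peaks (value ``nz * dz``) whenever ``c`` is a
    multiple of the frequency step ``1 / (nz dz)`` times ``nz`` ... i.e. it is
    the periodic sinc of the sampled exponential.  Accepts any real array.
    """
    c = np.asarray(c, dtype=float)
    z0 = -(nz // 2) * dz
    phase = np.exp(1j * 2.0 * np.pi * c * dz)
    lead = np.exp(1j * 2.0 * np.pi * c * z0)
    num = phase**nz - 1.0
    den = phase - 1.0
    small = np.abs(den) < 1e-12
    ratio = np.where(small, nz + 0.0j, np.where(small, 1.0, num) / np.where(small, 1.0, den))
    return dz * lead * ratio


def source_eta(nu_perp: tuple[float, float], grid: GridSpec) -> float:
    """Axial frequency of an illumination plane wave, snapped to the uz grid.

    Snapping makes the sampled incident phase exactly periodic over the z
    window, so the transfer-function set is the exact linearization of the
    FFT-based scattering simulator (no axial wrap-around inconsistency).  The
    quantization moves each source off the exact Ewald sphere by at most half
    an axial frequency step, 1/(2 nz dz).
    """
    nu_y, nu_x = nu_perp
    eta = np.sqrt(grid.medium_frequency**2 - nu_y**2 - nu_x**2)
    duz = 1.0 / (grid.shape[0] * grid.spacing[0])
    return float(np.round(eta / duz) * duz)


def propagation_eta(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """(eta, propagating mask) over the transverse frequency grid.

    ``eta = sqrt((n_m/lambda0)^2 - |u_perp|^2)`` on the propagating band,
    0 elsewhere.
    """
    uy, ux = grid.transverse_freq_grids()
    numax = grid.medium_frequency
    rho_sq = uy**2 + ux**2
    arg = numax**2 - rho_sq
    prop = arg > (1e-6 * numax) ** 2
    eta = np.sqrt(np.where(prop, arg, 0.0))
    return eta, prop


def transverse_green(
    grid: GridSpec, na_cutoff: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transverse part of the dyadic angular-spectrum propagator.

    Returns ``(Q, eta, mask)`` where ``Q[p, q, iy, ix]`` is
    ``i / (4 pi eta) * (I - s s^T)`` with ``s`` the unit propagation
    direction, zeroed outside the cutoff, ``eta`` the axial frequency and
    ``mask`` the admitted band.  The full 3D spectrum is
    ``Q * dirichlet_kernel(eta - u_z)``.
    """
    eta, prop = propagation_eta(grid)
    if na_cutoff is not None:
        uy, ux = grid.transverse_freq_grids()
        prop = prop & (uy**2 + ux**2 <= (na_cutoff / grid.wavelength_um) ** 2)
    uy, ux = grid.transverse_freq_grids()
    numax = grid.medium_frequency
    with np.errstate(divide="ignore", invalid="ignore"):
        sx = np.where(prop, ux / numax, 0.0) * np.ones_like(eta)
        sy = np.where(prop, uy / numax, 0.0) * np.ones_like(eta)
        sz = np.where(prop, eta / numax, 0.0)
    s = np.stack([sx, sy, sz])
    proj = np.eye(3)[:, :, None, None] - s[:, None] * s[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = np.where(prop, 1.0 / (4.0 * np.pi * np.where(prop, eta, 1.0)), 0.0)
    Q = 1j * pref[None, None] * proj
    Q[:, :, ~prop] = 0.0
    return Q, eta, prop


def incident_polarization(
    nu_perp: tuple[float, float], grid: GridSpec, handedness: str = "rcp"
) -> np.ndarray:
    """Unit Jones vector of circular polarization transported to direction nu.

    The paraxial states ``x_hat`` and ``y_hat`` are carried onto the
    illumination sphere along meridians (s/p decomposition); right circular is
    ``(x - i y)/sqrt(2)`` (S3 = -1), left is ``(x + i y)/sqrt(2)``.

    Parameters
    ----------
    nu_perp : (nu_y, nu_x) transverse spatial frequency in 1/um.
    """
    nu_y, nu_x = nu_perp
    numax = grid.medium_frequency
    rho = float(np.hypot(nu_x, nu_y))
    if rho >= numax:
        raise ValueError(f"evanescent illumination frequency |nu|={rho:.3f} >= {numax:.3f}")
    sin_b = rho / numax
    cos_b = float(np.sqrt(1.0 - sin_b**2))
    phi = float(np.arctan2(nu_y, nu_x)) if rho > 0 else 0.0
    cp, sp_ = np.cos(phi), np.sin(phi)
    e_theta = np.array([cos_b * cp, cos_b * sp_, -sin_b])
    e_phi = np.array([-sp_, cp, 0.0])
    ex = cp * e_theta - sp_ * e_phi   # transported x_hat
    ey = sp_ * e_theta + cp * e_phi   # transported y_hat
    if handedness == "rcp":
        return (ex - 1j * ey) / np.sqrt(2.0)
    if handedness == "lcp":
        return (ex + 1j * ey) / np.sqrt(2.0)
    raise ValueError(f"unknown handedness {handedness!r}")
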