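"""Uniaxial permittivity-tensor algebra.

A uniaxial dielectric voxel is parameterized by its mean relative
permittivity ``eps_mean``, signed differential permittivity ``delta_eps``,
in-plane orientation ``omega`` and inclination ``theta`` of the symmetry
axis.  The tensor is

    eps = n_o**2 * I + 2 * delta_eps * outer(a, a),

with axis ``a = (sin(theta)cos(omega), sin(theta)sin(omega), cos(theta))``,
``n_o**2 = eps_mean - delta_eps`` and ``n_e**2 = eps_mean + delta_eps``.

The scattering potential tensor ``k0**2 (eps - eps_rm * I)`` is decomposed
into seven real scalar volumes ``f0r, f0i, f1c, f1s, f2c, f2s, f3`` whose
angular dependence isolates the isotropic part, the doubled in-plane angle,
the single in-plane angle and the inclination.  This module provides the
forward decomposition and the closed-form inverse extraction under a
positive or negative uniaxial assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "UniaxialField",
    "ScatteringPotential",
    "COMPONENT_NAMES",
    "TENSOR_BASIS",
    "moments_from_indices",
    "indices_from_moments",
    "permittivity_matrix",
    "scattering_potential_from_material",
    "material_from_scattering_potential",
    "out_of_plane_tilt",
    "wrap_orientation",
]

#: order of the scalar components of the scattering potential tensor
COMPONENT_NAMES = ("f0r", "f0i", "f1c", "f1s", "f2c", "f2s", "f3")

#: 3x3 basis matrices T_l such that  f_tensor = sum_l f_l * T_l
TENSOR_BASIS = np.zeros((7, 3, 3), dtype=complex)
TENSOR_BASIS[0] = np.eye(3)                    # f0r
TENSOR_BASIS[1] = 1j * np.eye(3)               # f0i (absorption)
TENSOR_BASIS[2] = np.diag([1.0, -1.0, 0.0])    # f1c
TENSOR_BASIS[3, 0, 1] = TENSOR_BASIS[3, 1, 0] = 1.0  # f1s
TENSOR_BASIS[4, 0, 2] = TENSOR_BASIS[4, 2, 0] = 1.0  # f2c
TENSOR_BASIS[5, 1, 2] = TENSOR_BASIS[5, 2, 1] = 1.0  # f2s
TENSOR_BASIS[6, 2, 2] = 1.0                    # f3
TENSOR_BASIS.setflags(write=False)


@dataclass(frozen=True)
class GridSpec:
    """Sampling grid, wavelength and immersion medium of one acquisition.

    Parameters
    ----------
    shape : (nz, ny, nx) voxel counts.
    spacing : (dz, dy, dx) voxel size in micrometres.
    wavelength_um : free-space wavelength in micrometres.
    medium_index : refractive index of the surrounding medium.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    wavelength_um: float
    medium_index: float

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(d <= 0 for d in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be > 0")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(d) for d in self.spacing))

    @property
    def k0(self) -> float:
        """Free-space wavenumber 2*pi/lambda0 (rad / um)."""
        return 2.0 * np.pi / self.wavelength_um

    @property
    def eps_rm(self) -> float:
        """Relative permittivity of the immersion medium."""
        return self.medium_index**2

    @property
    def medium_frequency(self) -> float:
        """Magnitude of the propagating spatial frequency n_m/lambda0 (1/um)."""
        return self.medium_index / self.wavelength_um

    # --- coordinate helpers -------------------------------------------------
    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Centered spatial coordinates (z, y, x) in um, origin at index n//2."""
        return tuple(
            (np.arange(n) - n // 2) * d for n, d in zip(self.shape, self.spacing)
        )

    def freqs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """FFT-ordered spatial frequencies (uz, uy, ux) in 1/um."""
        return tuple(
            np.fft.fftfreq(n, d) for n, d in zip(self.shape, self.spacing)
        )

    def transverse_freq_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcastable (uy, ux) frequency grids, FFT order."""
        _, uy, ux = self.freqs()
        return uy[:, None], ux[None, :]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


def wrap_orientation(
    omega: np.ndarray, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Canonicalize an axis parameterization to omega in [0, 2 pi), theta in
    [0, pi/2] (upper-hemisphere axis convention).

    Uses the exact axis identification (omega, theta) == (omega + pi,
    pi - theta): folding an axis pointing into the lower hemisphere onto its
    antipode leaves the permittivity tensor unchanged.  The azimuth keeps its
    full 2 pi range; restricting it to [0, pi) would silently flip the sign
    of the single-angle tensor components for half of all axes.
    """
    omega = np.asarray(omega, dtype=float).copy()
    theta = np.asarray(theta, dtype=float) % np.pi
    fold = theta > np.pi / 2
    theta = np.where(fold, np.pi - theta, theta)
    omega = np.where(fold, omega + np.pi, omega)
    omega = omega % (2.0 * np.pi)
    return omega, theta


@dataclass
class UniaxialField:
    """Per-voxel uniaxial material parameters on a common grid.

    ``validate=False`` skips the physicality checks; reconstructed estimates
    may transiently violate positive definiteness in noisy voxels.
    """

    eps_mean: np.ndarray
    delta_eps: np.ndarray
    omega: np.ndarray  # axis azimuth, canonicalized to [0, 2 pi)
    theta: np.ndarray  # axis inclination from +z, canonicalized to [0, pi/2]
    validate: bool = True

    def __post_init__(self) -> None:
        self.eps_mean = np.asarray(self.eps_mean, dtype=float)
        self.delta_eps = np.asarray(self.delta_eps, dtype=float)
        if self.eps_mean.shape != self.delta_eps.shape:
            raise ValueError("eps_mean and delta_eps shapes differ")
        om = np.broadcast_to(np.asarray(self.omega, dtype=float), self.eps_mean.shape)
        th = np.broadcast_to(np.asarray(self.theta, dtype=float), self.eps_mean.shape)
        self.omega, self.theta = wrap_orientation(om, th)
        if self.validate:
            if np.any(self.eps_mean <= 0):
                raise ValueError("eps_mean must be positive everywhere")
            if np.any(np.abs(self.delta_eps) >= self.eps_mean):
                raise ValueError("|delta_eps| must be < eps_mean (positive definiteness)")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.eps_mean.shape

    @property
    def n_o(self) -> np.ndarray:
        return np.sqrt(self.eps_mean - self.delta_eps)

    @property
    def n_e(self) -> np.ndarray:
        return np.sqrt(self.eps_mean + self.delta_eps)

    @property
    def optic_sign(self) -> np.ndarray:
        return np.sign(self.delta_eps)

    def axis(self) -> np.ndarray:
        """Unit symmetry axis, shape (3,) + field shape (x, y, z ordering)."""
        st = np.sin(self.theta)
        return np.stack(
            [st * np.cos(self.omega), st * np.sin(self.omega), np.cos(self.theta)]
        )


@dataclass
class ScatteringPotential:
    """Seven scalar component volumes of the scattering potential tensor (um^-2)."""

    components: np.ndarray  # (7,) + grid.shape
    grid: GridSpec

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        expected = (7,) + tuple(self.grid.shape)
        if self.components.shape != expected:
            raise ValueError(
                f"components shape {self.components.shape} != {expected}"
            )
        if not np.all(np.isfinite(self.components)):
            raise ValueError("scattering potential components must be finite")

    def __getattr__(self, name: str) -> np.ndarray:
        if name in COMPONENT_NAMES:
            return self.components[COMPONENT_NAMES.index(name)]
        raise AttributeError(name)

    def tensor(self) -> np.ndarray:
        """Assemble the full 3x3 tensor field, shape grid.shape + (3, 3)."""
        return np.einsum("l...,lij->...ij", self.components, TENSOR_BASIS.real) + (
            1j * np.einsum("l...,lij->...ij", self.components, TENSOR_BASIS.imag)
        )


# ---------------------------------------------------------------------------
# moment / index maps
# ---------------------------------------------------------------------------

def moments_from_indices(n_o, n_e):
    """(n_o, n_e) -> (eps_mean, delta_eps) = ((ne^2+no^2)/2, (ne^2-no^2)/2)."""
    n_o = np.asarray(n_o, dtype=float)
    n_e = np.asarray(n_e, dtype=float)
    if np.any(n_o <= 0) or np.any(n_e <= 0):
        raise ValueError("refractive indices must be positive")
    return 0.5 * (n_e**2 + n_o**2), 0.5 * (n_e**2 - n_o**2)


def indices_from_moments(eps_mean, delta_eps):
    """Inverse of :func:`moments_from_indices`; requires eps_mean > |delta_eps|."""
    eps_mean = np.asarray(eps_mean, dtype=float)
    delta_eps = np.asarray(delta_eps, dtype=float)
    if np.any(eps_mean <= np.abs(delta_eps)):
        raise ValueError("need eps_mean > |delta_eps| for real indices")
    return np.sqrt(eps_mean - delta_eps), np.sqrt(eps_mean + delta_eps)


def permittivity_matrix(eps_mean, delta_eps, omega, theta) -> np.ndarray:
    """3x3 symmetric relative permittivity tensor(s) of uniaxial voxels.

    Broadcasts over leading dimensions; returns shape ``(..., 3, 3)``.
    Eigenvalues are {n_o^2 (twice), n_e^2}; the non-degenerate eigenvector is
    the symmetry axis.
    """
    eps_mean, delta_eps, omega, theta = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (eps_mean, delta_eps, omega, theta))
    )
    st, ct = np.sin(theta), np.cos(theta)
    axis = np.stack([st * np.cos(omega), st * np.sin(omega), ct], axis=-1)
    n_o_sq = eps_mean - delta_eps
    eye = np.eye(3)
    return (
        n_o_sq[..., None, None] * eye
        + 2.0 * delta_eps[..., None, None] * axis[..., :, None] * axis[..., None, :]
    )


def out_of_plane_tilt(theta):
    """Tilt of the symmetry axis out of the x-y plane: |theta - pi/2|."""
    return np.abs(np.asarray(theta, dtype=float) - np.pi / 2)


# ---------------------------------------------------------------------------
# forward decomposition
# ---------------------------------------------------------------------------

def scattering_potential_from_material(
    field: UniaxialField, grid: GridSpec
) -> ScatteringPotential:
    """Decompose a uniaxial field into the seven scattering-potential volumes.

    ``f0r = k0^2 (eps_mean - eps_rm - delta_eps cos^2 theta)`` and the five
    anisotropic components carry ``delta_eps`` modulated by the doubled /
    single in-plane angle and the inclination.  ``f0i`` is zero (transparent
    specimens).
    """
    if tuple(field.shape) != tuple(grid.shape):
        raise ValueError(f"field shape {field.shape} != grid shape {grid.shape}")
    k0sq = grid.k0**2
    de = field.delta_eps
    st2 = np.sin(field.theta) ** 2
    s2t = np.sin(2.0 * field.theta)
    ct2 = np.cos(field.theta) ** 2
    comps = np.empty((7,) + tuple(grid.shape), dtype=float)
    comps[0] = k0sq * (field.eps_mean - grid.eps_rm - de * ct2)
    comps[1] = 0.0
    comps[2] = k0sq * de * st2 * np.cos(2.0 * field.omega)
    comps[3] = k0sq * de * st2 * np.sin(2.0 * field.omega)
    comps[4] = k0sq * de * s2t * np.cos(field.omega)
    comps[5] = k0sq * de * s2t * np.sin(field.omega)
    comps[6] = k0sq * de * (3.0 * ct2 - 1.0)
    return ScatteringPotential(comps, grid)


# ---------------------------------------------------------------------------
# inverse extraction
# ---------------------------------------------------------------------------

def material_from_scattering_potential(
    sp: ScatteringPotential,
    sign_assumption: int,
    grid: GridSpec | None = None,
    tol: float = 1e-8,
) -> UniaxialField:
    """Closed-form extraction of (eps contrast, delta_eps, omega, theta).

    Assumes every voxel is uniaxial with the given optic ``sign_assumption``
    (+1 or -1).  The five anisotropic components are assembled into the
    traceless-symmetric-like tensor part ``B`` (in units of ``delta_eps``)
    and eigendecomposed: for an exactly uniaxial voxel the symmetry axis is
    the non-degenerate eigenvector, with eigenvalue spread ``2 delta_eps``.
    Under the positive assumption the axis is the largest-eigenvalue
    direction, under the negative assumption the smallest.  The mean
    contrast follows as ``g0r + delta_eps cos^2 theta``.

    Degenerate (isotropic) voxels map to (contrast g0r, delta_eps 0, omega
    0, theta pi/2).  The returned ``eps_mean`` is the absolute permittivity
    ``eps_rm + contrast``.  Re-applying the forward decomposition to the
    output reproduces the five anisotropic inputs exactly whenever they are
    realizable with the assumed sign.
    """
    if sign_assumption not in (+1, -1):
        raise ValueError("sign_assumption must be +1 or -1")
    grid = grid or sp.grid
    s = float(sign_assumption)
    k0sq = grid.k0**2
    g = sp.components / k0sq
    g0r, _, g1c, g1s, g2c, g2s, g3 = g

    # anisotropic tensor part  B = 2 de a a^T - de sin^2(theta) I  for an
    # exactly uniaxial voxel; its eigen-spread is 2 de and the non-degenerate
    # eigenvector is the symmetry axis.  The eigen route uses all five
    # components symmetrically and stays stable when the anisotropy is purely
    # axial (only f3 nonzero).
    shape = g0r.shape
    B = np.empty(shape + (3, 3))
    B[..., 0, 0] = g1c
    B[..., 1, 1] = -g1c
    B[..., 2, 2] = g3
    B[..., 0, 1] = B[..., 1, 0] = g1s
    B[..., 0, 2] = B[..., 2, 0] = g2c
    B[..., 1, 2] = B[..., 2, 1] = g2s
    evals, evecs = np.linalg.eigh(B)  # ascending
    if s > 0:
        lam_axis = evals[..., 2]
        axis = evecs[..., :, 2]
        lam_perp = 0.5 * (evals[..., 0] + evals[..., 1])
    else:
        lam_axis = evals[..., 0]
        axis = evecs[..., :, 0]
        lam_perp = 0.5 * (evals[..., 1] + evals[..., 2])
    delta_eps = 0.5 * (lam_axis - lam_perp)

    degenerate = np.abs(delta_eps) <= tol
    ax, ay, az = axis[..., 0], axis[..., 1], axis[..., 2]
    theta = np.arccos(np.clip(np.abs(az), 0.0, 1.0))
    # canonical hemisphere: az > 0; for in-plane axes pick ay >= 0 (ax >= 0
    # on the remaining tie) so the representative is deterministic
    flip = (az < -tol) | ((np.abs(az) <= tol) & ((ay < -tol) | ((np.abs(ay) <= tol) & (ax < 0))))
    omega = np.arctan2(np.where(flip, -ay, ay), np.where(flip, -ax, ax)) % (2 * np.pi)
    delta_eps = np.where(degenerate, 0.0, delta_eps)
    theta = np.where(degenerate, np.pi / 2.0, theta)
    omega = np.where(degenerate, 0.0, omega)

    contrast = g0r + delta_eps * np.cos(theta) ** 2
    return UniaxialField(
        eps_mean=grid.eps_rm + contrast,
        delta_eps=delta_eps,
        omega=omega,
        theta=theta,
        validate=False,
    )
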