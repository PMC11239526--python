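"""Illumination patterns, pupils and vectorial transfer functions.

The linearized single-scattering model relates the DC-subtracted Stokes
spectra to the scattering-potential component spectra through a set of
transfer functions ``H[m, l, alpha](u)`` (Stokes channel m, tensor component
l, illumination pattern alpha).  They are assembled numerically by summing,
over every point source of a pattern, the two interference terms between the
incident plane wave and the Green's-tensor-filtered scattered response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._fourier import (
    dirichlet_kernel,
    incident_polarization,
    propagation_eta,
    source_eta,
    transverse_green,
)
from .tensor_core import COMPONENT_NAMES, TENSOR_BASIS, GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "IlluminationPattern",
    "DetectionSpec",
    "TransferFunctionSet",
    "sector_patterns",
    "greens_tensor_spectrum",
    "compute_transfer_functions",
    "project_otf_2d",
]


@dataclass
class IlluminationPattern:
    """Weights of mutually incoherent point sources on the transverse
    frequency grid (FFT order), plus the incident polarization state."""

    source_weights: np.ndarray  # (ny, nx) float, >= 0
    polarization: str = "rcp"
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.source_weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("source weights must be non-negative")
        if not np.any(w > 0):
            raise ValueError("pattern has no active source")
        self.source_weights = w

    @property
    def total_weight(self) -> float:
        return float(self.source_weights.sum())


@dataclass(frozen=True)
class DetectionSpec:
    """Objective NA and the four linear analyzer orientations (degrees)."""

    na_obj: float
    analyzer_angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)

    def __post_init__(self) -> None:
        if self.na_obj <= 0:
            raise ValueError("na_obj must be positive")
        if len(set(round(a % 180.0, 9) for a in self.analyzer_angles)) != len(
            self.analyzer_angles
        ):
            raise ValueError("analyzer angles must be distinct modulo 180 deg")


def sector_patterns(
    grid: GridSpec,
    na_illu: float,
    n_sectors: int = 8,
    sector_width_deg: float = 90.0,
    include_brightfield: bool = True,
    na_inner: float | None = None,
    source_stride: int = 1,
) -> list[IlluminationPattern]:
    """Default illumination plan: one brightfield disk plus rotated sectors.

    With defaults this builds 9 patterns: a full disk of radius ``na_illu``
    and 8 annular sectors of 90 deg width at 45 deg steps (inner radius
    ``0.3 * na_illu``).  ``source_stride`` subsamples the pupil-grid source
    points (identical lattice for every pattern), trading accuracy for speed.
    """
    if n_sectors < 3:
        raise ValueError("need n_sectors >= 3")
    if na_inner is None:
        na_inner = 0.3 * na_illu
    if not (0 <= na_inner < na_illu):
        raise ValueError(f"need 0 <= na_inner < na_illu, got {na_inner} vs {na_illu}")
    ny, nx = grid.shape[1], grid.shape[2]
    uy, ux = grid.transverse_freq_grids()
    rho = np.hypot(uy, ux) * np.ones((ny, nx))
    _, prop = propagation_eta(grid)
    r_out = na_illu / grid.wavelength_um
    r_in = na_inner / grid.wavelength_um
    lattice = np.zeros((ny, nx), dtype=bool)
    iy = np.arange(ny) % source_stride == 0  # index 0 is the on-axis source
    ix = np.arange(nx) % source_stride == 0
    lattice[np.ix_(iy, ix)] = True
    disk = (rho <= r_out) & prop & lattice

    patterns: list[IlluminationPattern] = []
    if include_brightfield:
        patterns.append(
            IlluminationPattern(disk.astype(float), label="brightfield")
        )
    phi = np.degrees(np.arctan2(uy, ux)) * np.ones((ny, nx))
    annulus = disk & (rho >= r_in)
    step = 360.0 / n_sectors
    for k in range(n_sectors):
        center = k * step
        dphi = (phi - center + sector_width_deg / 2.0) % 360.0
        mask = annulus & (dphi < sector_width_deg)
        patterns.append(
            IlluminationPattern(mask.astype(float), label=f"sector{k:02d}")
        )
    return patterns


def greens_tensor_spectrum(
    grid: GridSpec, na_cutoff: float | None = None
) -> np.ndarray:
    """Dyadic Green's tensor spectrum, shape (3, 3, nz, ny, nx), complex.

    Per transverse frequency inside the cutoff the tensor is the transverse
    projector ``I - s s^T`` times the scalar angular-spectrum propagator
    ``i/(4 pi eta)`` times the finite-window axial kernel peaked at
    ``u_z = eta``.  Evanescent frequencies are zero.
    """
    Q, eta, _ = transverse_green(grid, na_cutoff)
    nz = grid.shape[0]
    dz = grid.spacing[0]
    uz = np.fft.fftfreq(nz, dz)
    D = dirichlet_kernel(eta[None] - uz[:, None, None], nz, dz)
    return Q[:, :, None] * D[None, None]


@dataclass
class TransferFunctionSet:
    """Transfer functions H[m, l, alpha] over the (3D or 2D) frequency grid."""

    H: np.ndarray  # (3, 7, n_alpha, nz, ny, nx) or (3, 7, n_alpha, ny, nx)
    grid: GridSpec
    patterns: list[IlluminationPattern]
    detection: DetectionSpec
    meta: dict = field(default_factory=dict)

    @property
    def n_patterns(self) -> int:
        return self.H.shape[2]

    @property
    def is_2d(self) -> bool:
        return self.H.ndim == 5

    def apply(self, component_spectra: np.ndarray) -> np.ndarray:
        """Sum_l H[m,l,alpha] * f~_l -> Stokes spectra (alpha, m, ...)."""
        out = np.einsum("mla...,l...->am...", self.H, component_spectra)
        return out


def _reversed_index(n: int) -> np.ndarray:
    return (-np.arange(n)) % n


def compute_transfer_functions(
    patterns: list[IlluminationPattern],
    detection: DetectionSpec,
    grid: GridSpec,
    dtype=np.complex64,
) -> TransferFunctionSet:
    """Assemble the vectorial transfer-function set for a pattern list.

    For every active source frequency nu the incident plane wave interferes
    with the scattered response of each tensor component; the two conjugate
    interference terms are accumulated per Stokes channel.  Each pattern is
    finally normalized by its background S0 so that the functions act on
    DC-normalized Stokes data.
    """
    nz, ny, nx = grid.shape
    dz = grid.spacing[0]
    uz = np.fft.fftfreq(nz, dz)
    uzc = uz[:, None, None]
    uy1d = np.fft.fftfreq(ny, grid.spacing[1])
    ux1d = np.fft.fftfreq(nx, grid.spacing[2])

    Q, eta, band = transverse_green(grid, na_cutoff=None)
    pupil = _detection_pupil(grid, detection)
    Q = Q * pupil[None, None]
    # only the x/y field rows reach the analyzer
    Qxy = Q[:2].astype(np.complex64)
    rev_y = _reversed_index(ny)
    rev_x = _reversed_index(nx)
    Qrev = Qxy[:, :, rev_y][:, :, :, rev_x]
    eta_rev = eta[rev_y][:, rev_x]

    n_alpha = len(patterns)
    H = np.zeros((3, 7, n_alpha, nz, ny, nx), dtype=dtype)
    bg_stokes = np.zeros((3, n_alpha))

    # union of active sources with per-pattern weights
    stack = np.stack([p.source_weights for p in patterns])
    active = np.argwhere(stack.sum(axis=0) > 0)
    basis = TENSOR_BASIS.astype(np.complex64)
    na_obj_freq = detection.na_obj / grid.wavelength_um

    logger.info("assembling transfer functions: %d sources, %d patterns", len(active), n_alpha)
    contrib = np.empty((3, 7, nz, ny, nx), dtype=np.complex64)
    for iy, ix in active:
        nu = (uy1d[iy], ux1d[ix])
        if np.hypot(*nu) >= grid.medium_frequency:
            continue
        e_hat = incident_polarization(nu, grid, patterns[0].polarization).astype(np.complex64)
        eta_nu = source_eta(nu, grid)
        blocked = np.hypot(*nu) > na_obj_freq  # darkfield source: no reference wave
        w_alpha = stack[:, iy, ix]
        if blocked:
            continue
        sxx, syy = abs(e_hat[0]) ** 2, abs(e_hat[1]) ** 2
        sxy = e_hat[0] * np.conj(e_hat[1])
        bg_stokes[0] += w_alpha * (sxx + syy)
        bg_stokes[1] += w_alpha * (sxx - syy)
        bg_stokes[2] += w_alpha * 2.0 * sxy.real

        # term 2: scattered spectrum observed at u + nu  (transverse roll)
        Q2 = np.roll(Qxy, (-iy, -ix), axis=(2, 3))
        eta2 = np.roll(eta, (-iy, -ix), axis=(0, 1))
        D2 = dirichlet_kernel(eta2[None] - uzc - eta_nu, nz, dz).astype(np.complex64)
        # term 1: conjugate response at nu - u
        Q1 = np.roll(Qrev, (iy, ix), axis=(2, 3))
        eta1 = np.roll(eta_rev, (iy, ix), axis=(0, 1))
        D1c = np.conj(
            dirichlet_kernel(eta1[None] - eta_nu + uzc, nz, dz)
        ).astype(np.complex64)

        for l in range(7):
            v = basis[l] @ e_hat
            a2 = np.einsum("pqyx,q->pyx", Q2, v)          # (2, ny, nx)
            a1c = np.conj(np.einsum("pqyx,q->pyx", Q1, v))
            ex_c, ey_c = np.conj(e_hat[0]), np.conj(e_hat[1])
            # H_pq = conj(e_q) a2_p D2 + e_p conj(a1_q) conj(D1)
            cxx2, cyy2 = ex_c * a2[0], ey_c * a2[1]
            cxy2, cyx2 = ey_c * a2[0], ex_c * a2[1]
            cxx1, cyy1 = e_hat[0] * a1c[0], e_hat[1] * a1c[1]
            cxy1, cyx1 = e_hat[0] * a1c[1], e_hat[1] * a1c[0]
            contrib[0, l] = (cxx2 + cyy2)[None] * D2 + (cxx1 + cyy1)[None] * D1c
            contrib[1, l] = (cxx2 - cyy2)[None] * D2 + (cxx1 - cyy1)[None] * D1c
            contrib[2, l] = (cxy2 + cyx2)[None] * D2 + (cxy1 + cyx1)[None] * D1c
        for a in np.nonzero(w_alpha)[0]:
            H[:, :, a] += w_alpha[a] * contrib

    for a in range(n_alpha):
        if bg_stokes[0, a] <= 0:
            raise ValueError(f"pattern {a} has zero background intensity")
        H[:, :, a] /= bg_stokes[0, a]
        # the background-corrected data channels are S1/S0 - S1_bg/S0_bg (same
        # for S2), which mix the S0 modulation into S1/S2 at first order with
        # the background polarization ratio; fold that into the model
        for m in (1, 2):
            ratio = bg_stokes[m, a] / bg_stokes[0, a]
            if ratio != 0.0:
                H[m, :, a] -= ratio * H[0, :, a]

    return TransferFunctionSet(
        H=H,
        grid=grid,
        patterns=patterns,
        detection=detection,
        meta={
            "n_sources": int(len(active)),
            "background_s0": bg_stokes[0].tolist(),
            "background_stokes": bg_stokes.tolist(),
        },
    )


def _detection_pupil(grid: GridSpec, detection: DetectionSpec) -> np.ndarray:
    uy, ux = grid.transverse_freq_grids()
    rho_sq = uy**2 + ux**2
    _, prop = propagation_eta(grid)
    return ((rho_sq <= (detection.na_obj / grid.wavelength_um) ** 2) & prop).astype(
        float
    )


def project_otf_2d(tfset: TransferFunctionSet) -> TransferFunctionSet:
    """Axially integrate a 3D set into the thin-specimen 2D transfer set.

    Each 2D function is the discrete integral ``sum_uz H * duz``; it maps the
    z-integrated component spectra to the focal-plane Stokes spectra.
    """
    if tfset.is_2d:
        raise ValueError("transfer-function set is already 2D")
    nz = tfset.grid.shape[0]
    duz = 1.0 / (nz * tfset.grid.spacing[0])
    H2 = tfset.H.sum(axis=3) * duz
    meta = dict(tfset.meta)
    meta["projected_2d"] = True
    return TransferFunctionSet(
        H=H2,
        grid=tfset.grid,
        patterns=tfset.patterns,
        detection=tfset.detection,
        meta=meta,
    )
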