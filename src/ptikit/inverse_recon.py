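"""Three-stage inverse algorithm.

Stage 1 solves, frequency by frequency, a Tikhonov-regularized least-squares
problem that stacks every (Stokes channel, illumination pattern) measurement
and estimates the seven scattering-potential component spectra.  Stage 2
extracts material properties twice, once under a positive and once under a
negative uniaxial assumption.  Stage 3 re-synthesizes the Stokes data from
both candidate solutions through the linear forward model and converts their
locally windowed residual energies into an optic-sign probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ._fourier import ft, ft2, ift, ift2
from .forward_sim import StokesData, simulate_linear_stokes
from .optics_otf import TransferFunctionSet
from .stokes_pipeline import (
    InstrumentMatrix,
    RawAcquisition,
    background_correct,
    instrument_matrix,
    intensities_to_stokes,
    normalize_dc,
)
from .tensor_core import (
    GridSpec,
    ScatteringPotential,
    UniaxialField,
    material_from_scattering_potential,
    scattering_potential_from_material,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReconstructionConfig",
    "PTIResult",
    "solve_components",
    "extract_properties",
    "estimate_optic_sign",
    "reconstruct",
]


@dataclass
class ReconstructionConfig:
    """Tuning knobs of the inverse algorithm.

    ``reg_iso``/``reg_aniso`` are dimensionless Tikhonov weights relative to
    the mean spectral power of the corresponding transfer-function channels.
    ``optic_sign_window`` is the smoothing radius (um) applied to the branch
    residual maps; ``min_anisotropy`` is the differential-permittivity floor
    below which the optic sign is left at 0.5.
    """

    reg_iso: float = 1e-4
    reg_aniso: float = 1e-4
    optic_sign_window: float = 0.5
    mode: str = "3D"
    min_anisotropy: float = 0.0

    def __post_init__(self) -> None:
        if self.reg_iso <= 0 or self.reg_aniso <= 0:
            raise ValueError("regularization weights must be > 0")
        if self.mode not in ("2D", "3D"):
            raise ValueError("mode must be '2D' or '3D'")


@dataclass
class PTIResult:
    """Reconstructed property maps."""

    mean_permittivity: np.ndarray  # eps_r - eps_rm
    diff_permittivity: np.ndarray  # |delta_eps|
    omega: np.ndarray
    theta: np.ndarray
    p_plus: np.ndarray
    grid: GridSpec | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.diff_permittivity < 0):
            raise ValueError("diff_permittivity must be non-negative")
        if np.any((self.p_plus < 0) | (self.p_plus > 1)):
            raise ValueError("p_plus must lie in [0, 1]")


def _stack_channels(tfset: TransferFunctionSet) -> np.ndarray:
    """H reshaped to (n_channels, 7, *freq_shape)."""
    H = tfset.H
    m, l, a = H.shape[:3]
    return np.transpose(H, (0, 2, 1) + tuple(range(3, H.ndim))).reshape(
        (m * a, l) + H.shape[3:]
    )


def solve_components(
    s_prime: StokesData, tfset: TransferFunctionSet, cfg: ReconstructionConfig
) -> ScatteringPotential:
    """Per-frequency closed-form Tikhonov solve for the seven components.

    Solves ``(H^H H + Lambda) f = H^H S'`` with all (m, alpha) channels
    stacked; ``Lambda`` is diagonal with ``reg_iso`` on the isotropic and
    ``reg_aniso`` on the anisotropic components, scaled by the mean diagonal
    spectral power so the weights are dimensionless.
    """
    grid = tfset.grid
    if s_prime.n_patterns < 2:
        raise ValueError("need at least 2 illumination patterns for conditioning")
    if s_prime.n_patterns != tfset.n_patterns:
        raise ValueError("pattern count mismatch between data and transfer functions")
    two_d = tfset.is_2d
    if two_d:
        if s_prime.S.ndim == 5 and s_prime.S.shape[2] != 1:
            raise ValueError("2D mode expects single-plane Stokes data")
        S = s_prime.S.reshape(s_prime.S.shape[:2] + s_prime.S.shape[-2:])
        Shat = ft2(S[:, :3], grid)
    else:
        if s_prime.S.shape[2:] != tuple(grid.shape):
            raise ValueError("Stokes volume shape does not match transfer-function grid")
        Shat = ft(s_prime.S[:, :3], grid)
    # data vector ordered to match _stack_channels: (m, alpha) -> m*a + ...
    b = np.transpose(Shat, (1, 0) + tuple(range(2, Shat.ndim)))
    b = b.reshape((-1,) + Shat.shape[2:])

    H = _stack_channels(tfset).astype(np.complex64)
    n_freq_axes = H.ndim - 2
    vol_axes = tuple(range(2, 2 + n_freq_axes))

    AtA = np.einsum("ci...,cj...->...ij", np.conj(H), H)
    Atb = np.einsum("ci...,c...->...i", np.conj(H), b.astype(np.complex64))

    diag_power = np.real(np.einsum("...ii->...i", AtA)).mean(
        axis=tuple(range(AtA.ndim - 3))
    )
    scale = max(float(diag_power.max()), np.finfo(float).tiny)
    lam = np.array(
        [cfg.reg_iso, cfg.reg_iso] + [cfg.reg_aniso] * 5, dtype=float
    ) * scale
    AtA[..., np.arange(7), np.arange(7)] += lam.astype(np.complex64)

    fhat = np.linalg.solve(
        AtA.astype(np.complex128), Atb.astype(np.complex128)[..., None]
    )[..., 0]
    fhat = np.moveaxis(fhat, -1, 0)
    if two_d:
        # the 2D solve estimates the z-integrated potential; park it on the
        # focal plane so that re-integration reproduces it exactly
        f = ift2(fhat, grid).real / grid.spacing[0]
        comps = np.zeros((7,) + tuple(grid.shape))
        comps[:, grid.shape[0] // 2] = f
    else:
        comps = ift(fhat, grid).real
    return ScatteringPotential(np.ascontiguousarray(comps), grid)


def extract_properties(
    sp: ScatteringPotential, grid: GridSpec | None = None
) -> tuple[UniaxialField, UniaxialField]:
    """Dual-branch algebraic property extraction (positive, negative)."""
    grid = grid or sp.grid
    plus = material_from_scattering_potential(sp, +1, grid)
    minus = material_from_scattering_potential(sp, -1, grid)
    return plus, minus


def _branch_residual(
    branch: UniaxialField,
    s_prime: StokesData,
    tfset: TransferFunctionSet,
) -> np.ndarray:
    sp_branch = scattering_potential_from_material(branch, tfset.grid)
    model = simulate_linear_stokes(sp_branch, tfset)
    S = s_prime.S[:, :3]
    M = model.S
    if S.ndim == 5 and M.ndim == 4:
        S = S.reshape(S.shape[:2] + S.shape[-2:])
    return np.sum((M - S) ** 2, axis=(0, 1))


def estimate_optic_sign(
    sp: ScatteringPotential,
    s_prime: StokesData,
    tfset: TransferFunctionSet,
    cfg: ReconstructionConfig,
) -> np.ndarray:
    """Optic-sign probability p_plus from branch residual energies.

    Each branch solution is recomposed into components, pushed through the
    linear forward model and compared with the measured S'.  With windowed
    residual energies r+ and r-, ``p_plus = r- / (r+ + r-)``; voxels with
    negligible anisotropy stay at 0.5.
    """
    plus, minus = extract_properties(sp)
    r_plus = _branch_residual(plus, s_prime, tfset)
    r_minus = _branch_residual(minus, s_prime, tfset)
    spacing = tfset.grid.spacing[-r_plus.ndim :]
    sigma = [max(cfg.optic_sign_window / d, 0.0) for d in spacing]
    r_plus = gaussian_filter(r_plus, sigma)
    r_minus = gaussian_filter(r_minus, sigma)
    total = r_plus + r_minus
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, r_minus / np.where(total > 0, total, 1.0), 0.5)
    aniso = np.maximum(np.abs(plus.delta_eps), np.abs(minus.delta_eps))
    if r_plus.ndim == 2 and aniso.ndim == 3:
        aniso = np.abs(aniso).max(axis=0)
    p = np.where(aniso <= cfg.min_anisotropy, 0.5, p)
    return np.clip(p, 0.0, 1.0)


def reconstruct(
    data: RawAcquisition | StokesData,
    background: RawAcquisition | StokesData | None,
    tfset: TransferFunctionSet,
    cfg: ReconstructionConfig | None = None,
    instrument: InstrumentMatrix | None = None,
) -> PTIResult:
    """Full pipeline: Stokes preprocessing, component solve, dual-branch
    property extraction and optic-sign estimation.

    ``data``/``background`` may be raw analyzer intensities (converted with
    the ideal or supplied instrument matrix) or Stokes volumes.  Per-voxel
    properties are taken from the branch favoured by the smoothed optic-sign
    probability (ties resolve to the positive branch).
    """
    cfg = cfg or ReconstructionConfig()
    if isinstance(data, RawAcquisition):
        A = instrument or instrument_matrix()
        stokes = intensities_to_stokes(data, A)
    else:
        stokes = data
    if background is not None:
        if isinstance(background, RawAcquisition):
            A = instrument or instrument_matrix()
            bg = intensities_to_stokes(background, A)
        else:
            bg = background
        stokes = background_correct(stokes, bg)
    s_prime = normalize_dc(stokes)

    sp = solve_components(s_prime, tfset, cfg)
    plus, minus = extract_properties(sp)
    p_plus = estimate_optic_sign(sp, s_prime, tfset, cfg)

    grid = tfset.grid
    take_plus = p_plus >= 0.5
    if p_plus.ndim == 2 and plus.delta_eps.ndim == 3:
        take_plus = np.broadcast_to(take_plus, plus.delta_eps.shape)
        p_map = p_plus
    else:
        p_map = p_plus
    mean_perm = np.where(
        take_plus, plus.eps_mean - grid.eps_rm, minus.eps_mean - grid.eps_rm
    )
    diff_perm = np.where(
        take_plus, np.abs(plus.delta_eps), np.abs(minus.delta_eps)
    )
    omega = np.where(take_plus, plus.omega, minus.omega)
    theta = np.where(take_plus, plus.theta, minus.theta)
    return PTIResult(
        mean_permittivity=mean_perm,
        diff_permittivity=diff_perm,
        omega=omega,
        theta=theta,
        p_plus=p_map,
        grid=grid,
        meta={"config": vars(cfg).copy()},
    )
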