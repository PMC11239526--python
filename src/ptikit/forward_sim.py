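"""Single-scattering vectorial forward simulator.

``born_scatter`` convolves the dyadic angular-spectrum propagator with the
induced source ``f_tensor . E_inc`` (first Born approximation); the detected
through-focus field is the incident wave plus the pupil-filtered scattered
wave.  ``simulate_stokes`` sums the coherency of the detected field over the
mutually incoherent point sources of each illumination pattern -- this is the
nonlinear reference model.  ``simulate_linear_stokes`` applies the
weak-object transfer functions instead and is exactly linear in the
scattering potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._fourier import (
    dirichlet_kernel,
    ft,
    ft2,
    ift,
    ift2,
    incident_polarization,
    source_eta,
    transverse_green,
)
from .optics_otf import (
    DetectionSpec,
    IlluminationPattern,
    TransferFunctionSet,
    _detection_pupil,
)
from .tensor_core import (
    GridSpec,
    ScatteringPotential,
    UniaxialField,
    scattering_potential_from_material,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VectorField",
    "StokesData",
    "incident_field",
    "born_scatter",
    "simulate_stokes",
    "simulate_background",
    "simulate_linear_stokes",
]


@dataclass
class VectorField:
    """Complex (E_x, E_y, E_z) volumes stacked along the first axis."""

    E: np.ndarray  # (3, nz, ny, nx) complex

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E)
        if self.E.ndim != 4 or self.E.shape[0] != 3:
            raise ValueError("E must have shape (3, nz, ny, nx)")

    @property
    def intensity(self) -> np.ndarray:
        return np.sum(np.abs(self.E) ** 2, axis=0)


@dataclass
class StokesData:
    """Stokes volumes S[alpha, m, z, y, x]; m runs over S0..S2 (+S3 in
    simulator output)."""

    S: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim not in (4, 5):
            raise ValueError("S must be (alpha, m, [z,] y, x)")
        if len(self.labels) != self.S.shape[0]:
            raise ValueError("one label per pattern required")

    @property
    def n_patterns(self) -> int:
        return self.S.shape[0]

    @property
    def n_stokes(self) -> int:
        return self.S.shape[1]


def incident_field(
    nu_perp: tuple[float, float], grid: GridSpec, polarization: str = "rcp"
) -> VectorField:
    """Unit-amplitude tilted plane wave with transported circular polarization.

    The axial frequency is grid-snapped (see :func:`ptikit._fourier.source_eta`)
    so that the sampled phase is periodic over the z window.
    """
    e_hat = incident_polarization(nu_perp, grid, polarization)
    eta_nu = source_eta(nu_perp, grid)
    z, y, x = grid.coords()
    phase = np.exp(
        1j
        * 2.0
        * np.pi
        * (
            nu_perp[1] * x[None, None, :]
            + nu_perp[0] * y[None, :, None]
            + eta_nu * z[:, None, None]
        )
    )
    return VectorField(e_hat[:, None, None, None] * phase[None])


def _apply_tensor(sp: ScatteringPotential, E: np.ndarray) -> np.ndarray:
    """Pointwise f_tensor . E without materializing the 3x3 field."""
    f0 = sp.components[0] + 1j * sp.components[1]
    f1c, f1s, f2c, f2s, f3 = sp.components[2:]
    Ex, Ey, Ez = E
    Vx = (f0 + f1c) * Ex + f1s * Ey + f2c * Ez
    Vy = f1s * Ex + (f0 - f1c) * Ey + f2s * Ez
    Vz = f2c * Ex + f2s * Ey + (f0 + f3) * Ez
    return np.stack([Vx, Vy, Vz])


class _Propagator:
    """Cached factored Green's spectrum for repeated scattering solves."""

    def __init__(self, grid: GridSpec, na_cutoff: float | None = None):
        self.grid = grid
        Q, eta, _ = transverse_green(grid, na_cutoff)
        nz, dz = grid.shape[0], grid.spacing[0]
        uz = np.fft.fftfreq(nz, dz)
        self.Q = Q.astype(np.complex64)
        self.D = dirichlet_kernel(eta[None] - uz[:, None, None], nz, dz).astype(
            np.complex64
        )

    def scatter(self, V: np.ndarray) -> np.ndarray:
        W = ft(V, self.grid)
        W = np.einsum("pqyx,qzyx->pzyx", self.Q, W)
        W *= self.D[None]
        return ift(W, self.grid)


def born_scatter(
    sp: ScatteringPotential,
    e_inc: VectorField,
    grid: GridSpec,
    na_cutoff: float | None = None,
) -> VectorField:
    """First-Born scattered-plus-incident field for one coherent illumination."""
    if e_inc.E.shape[1:] != tuple(grid.shape):
        raise ValueError("incident field shape does not match grid")
    prop = _Propagator(grid, na_cutoff)
    V = _apply_tensor(sp, e_inc.E)
    return VectorField(e_inc.E + prop.scatter(V))


def _coherency_terms(Ex: np.ndarray, Ey: np.ndarray):
    sxx = np.abs(Ex) ** 2
    syy = np.abs(Ey) ** 2
    sxy = Ex * np.conj(Ey)
    return sxx, syy, sxy


def _sources_union(patterns: list[IlluminationPattern]) -> tuple[np.ndarray, np.ndarray]:
    stack = np.stack([p.source_weights for p in patterns])
    active = np.argwhere(stack.sum(axis=0) > 0)
    return stack, active


def simulate_stokes(
    specimen: UniaxialField | ScatteringPotential,
    patterns: list[IlluminationPattern],
    detection: DetectionSpec,
    grid: GridSpec,
    keep_s3: bool = True,
) -> StokesData:
    """Nonlinear vector-Born Stokes volumes for every illumination pattern.

    The scattered field of every source point is low-pass filtered by the
    objective pupil, added to the incident wave, and its coherency is summed
    incoherently within each pattern.
    """
    if isinstance(specimen, UniaxialField):
        sp = scattering_potential_from_material(specimen, grid)
    else:
        sp = specimen
    nz, ny, nx = grid.shape
    prop = _Propagator(grid)
    pupil = _detection_pupil(grid, detection)
    uy1d = np.fft.fftfreq(ny, grid.spacing[1])
    ux1d = np.fft.fftfreq(nx, grid.spacing[2])
    na_obj_freq = detection.na_obj / grid.wavelength_um

    stack, active = _sources_union(patterns)
    n_m = 4 if keep_s3 else 3
    S = np.zeros((len(patterns), n_m, nz, ny, nx))
    logger.info("vector Born simulation: %d sources, %d patterns", len(active), len(patterns))
    for iy, ix in active:
        nu = (uy1d[iy], ux1d[ix])
        if np.hypot(*nu) >= grid.medium_frequency:
            continue
        e_inc = incident_field(nu, grid, patterns[0].polarization)
        V = _apply_tensor(sp, e_inc.E.astype(np.complex64))
        E_s = prop.scatter(V)
        # detection: transverse low-pass of the scattered wave
        Es_hat = np.fft.fft2(E_s, axes=(-2, -1))
        Es_hat *= pupil[None, None]
        E_s = np.fft.ifft2(Es_hat, axes=(-2, -1))
        if np.hypot(*nu) <= na_obj_freq:
            E = e_inc.E + E_s
        else:
            E = E_s  # darkfield source: unscattered beam blocked
        sxx, syy, sxy = _coherency_terms(E[0], E[1])
        w_alpha = stack[:, iy, ix]
        for a in np.nonzero(w_alpha)[0]:
            w = w_alpha[a]
            S[a, 0] += w * (sxx + syy)
            S[a, 1] += w * (sxx - syy)
            S[a, 2] += w * 2.0 * sxy.real
            if keep_s3:
                S[a, 3] += w * (-2.0) * sxy.imag
    return StokesData(S, [p.label for p in patterns])


def simulate_background(
    patterns: list[IlluminationPattern],
    detection: DetectionSpec,
    grid: GridSpec,
    keep_s3: bool = True,
) -> StokesData:
    """Empty-field (specimen-free) Stokes acquisition, one z-plane per pattern."""
    stack, active = _sources_union(patterns)
    uy1d = np.fft.fftfreq(grid.shape[1], grid.spacing[1])
    ux1d = np.fft.fftfreq(grid.shape[2], grid.spacing[2])
    na_obj_freq = detection.na_obj / grid.wavelength_um
    n_m = 4 if keep_s3 else 3
    S = np.zeros((len(patterns), n_m, 1, 1, 1))
    for iy, ix in active:
        nu = (uy1d[iy], ux1d[ix])
        if np.hypot(*nu) >= grid.medium_frequency or np.hypot(*nu) > na_obj_freq:
            continue
        e = incident_polarization(nu, grid, patterns[0].polarization)
        sxx, syy, sxy = abs(e[0]) ** 2, abs(e[1]) ** 2, e[0] * np.conj(e[1])
        vals = [sxx + syy, sxx - syy, 2.0 * sxy.real]
        if keep_s3:
            vals.append(-2.0 * sxy.imag)
        w_alpha = stack[:, iy, ix]
        for a in np.nonzero(w_alpha)[0]:
            for m, v in enumerate(vals):
                S[a, m] += w_alpha[a] * v
    S = np.broadcast_to(S, (len(patterns), n_m, 1, grid.shape[1], grid.shape[2])).copy()
    return StokesData(S, [p.label for p in patterns])


def simulate_linear_stokes(
    sp: ScatteringPotential, tfset: TransferFunctionSet
) -> StokesData:
    """Weak-object (linearized) forward model: DC-subtracted Stokes volumes."""
    if tuple(sp.grid.shape) != tuple(tfset.grid.shape):
        raise ValueError("scattering potential and transfer functions use different grids")
    if tfset.is_2d:
        dz = sp.grid.spacing[0]
        f2d = sp.components.sum(axis=1) * dz  # z-integrated thin-specimen potential
        fhat = ft2(f2d, sp.grid)
        Shat = tfset.apply(fhat)
        S = ift2(Shat, sp.grid).real
    else:
        fhat = ft(sp.components, sp.grid)
        Shat = tfset.apply(fhat)
        S = ift(Shat, sp.grid).real
    return StokesData(S, [p.label for p in tfset.patterns])
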