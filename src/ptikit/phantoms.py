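"""Synthetic specimens with exact ground truth.

Every generator returns a :class:`~ptikit.tensor_core.UniaxialField` on the
requested grid; the field itself is the ground truth consumed by the tests
and the acceptance experiments.  Geometry is hard-voxelized by default so
analytic volume counts are exact; generators are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .tensor_core import GridSpec, UniaxialField, moments_from_indices

__all__ = [
    "PhantomSpec",
    "star_target",
    "bead_phantom",
    "tube_phantom",
]

#: validity box of the weak-scattering regime explored in the simulations
#: (mean-permittivity contrast, differential permittivity); generators warn
#: beyond it.
WEAK_REGIME_MAX_CONTRAST = 0.2
WEAK_REGIME_MAX_DELTA = 0.05


@dataclass
class PhantomSpec:
    """Declarative phantom description (used by the CLI)."""

    kind: str
    grid: GridSpec
    geometry: dict = dc_field(default_factory=dict)
    optics: dict = dc_field(default_factory=dict)
    seed: int = 0

    def build(self) -> UniaxialField:
        builders = {
            "star": star_target,
            "bead": bead_phantom,
            "tube": tube_phantom,
        }
        if self.kind not in builders:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        return builders[self.kind](self.grid, **self.geometry, **self.optics)


def _warn_regime(contrast: float, delta: float) -> None:
    import warnings

    if abs(contrast) > WEAK_REGIME_MAX_CONTRAST or abs(delta) > WEAK_REGIME_MAX_DELTA:
        warnings.warn(
            f"phantom contrast ({contrast:.3g}, {delta:.3g}) exceeds the "
            "weak-scattering validity regime",
            stacklevel=3,
        )


def star_target(
    grid: GridSpec,
    n_wedges: int = 8,
    inner_radius_um: float = 0.5,
    outer_radius_um: float = 2.5,
    thickness_um: float | None = None,
    line_spacing_um: float | None = None,
    line_width_um: float | None = None,
    n_o: float = 1.525,
    n_e: float = 1.55,
    sign: int = +1,
    theta_deg: float = 90.0,
    sweep_inclination: bool = False,
) -> UniaxialField:
    """Star target of equally spaced uniform-orientation birefringent wedges.

    Adjacent wedges rotate by ``360/n_wedges`` degrees; within a wedge the
    symmetry axis is uniform, along the spoke for ``sign=+1`` and orthogonal
    to it for ``sign=-1``.  With ``line_spacing_um`` set, each wedge is
    filled with thin lines parallel to the spoke direction (the laser-written
    star geometry) instead of solid material.  With ``sweep_inclination`` the
    wedge inclination additionally steps from in-plane toward the axis across
    wedges.

    ``n_o``/``n_e`` always denote ordinary < extraordinary magnitudes of the
    written material; ``sign`` selects which axis is the symmetry axis.
    """
    if n_wedges < 2:
        raise ValueError("need n_wedges >= 2")
    if not 0 <= inner_radius_um < outer_radius_um:
        raise ValueError("radii must satisfy 0 <= inner < outer")
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    eps_mean, delta = moments_from_indices(n_o, n_e)
    delta = sign * abs(delta)
    _warn_regime(eps_mean - grid.eps_rm, delta)

    nz, ny, nx = grid.shape
    z, y, x = grid.coords()
    Z = z[:, None, None]
    Y = y[None, :, None]
    X = x[None, None, :]
    rho = np.sqrt(Y**2 + X**2) * np.ones((nz, 1, 1))
    if thickness_um is None:
        thickness_um = grid.spacing[0] * max(nz // 4, 1)
    in_slab = np.abs(Z) <= thickness_um / 2.0
    in_annulus = (rho >= inner_radius_um) & (rho <= outer_radius_um)
    mask = in_slab & in_annulus

    step = 2.0 * np.pi / n_wedges
    azimuth = np.arctan2(Y, X) % (2.0 * np.pi) * np.ones((nz, 1, 1))
    wedge = np.floor(azimuth / step).astype(int)
    spoke_dir = (wedge + 0.5) * step  # orientation of the wedge centerline
    omega = spoke_dir if sign > 0 else spoke_dir + np.pi / 2.0
    if line_spacing_um is not None:
        if line_width_um is None:
            line_width_um = line_spacing_um / 3.0
        # thin lines parallel to the spoke direction within each wedge
        perp = -np.sin(spoke_dir) * X + np.cos(spoke_dir) * Y
        mask = mask & (np.abs(perp % line_spacing_um) < line_width_um)
    theta = np.full(grid.shape, np.radians(theta_deg))
    if sweep_inclination:
        theta = np.radians(90.0 - 60.0 * wedge / max(n_wedges - 1, 1))

    eps = np.full(grid.shape, grid.eps_rm, dtype=float)
    de = np.zeros(grid.shape)
    eps[mask] = eps_mean
    de[mask] = delta
    om = np.where(mask, omega, 0.0)
    th = np.where(mask, theta, np.pi / 2.0)
    return UniaxialField(eps, de, om, th)


def bead_phantom(
    grid: GridSpec,
    diameter_um: float,
    n_bead: float | None = None,
    delta_eps: float = 0.0,
    eps_mean: float | None = None,
    axis: tuple[float, float] = (0.0, np.pi / 2.0),
    center_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
    antialias: bool = False,
) -> UniaxialField:
    """Voxelized sphere with optional uniform anisotropy at a fixed 3D axis.

    ``axis`` is (omega, theta) in radians.  Provide either ``n_bead`` (mean
    index) or ``eps_mean`` directly; ``delta_eps`` is the signed differential
    permittivity of the bead material.
    """
    if diameter_um < 2 * min(grid.spacing):
        raise ValueError("bead diameter must span at least 2 voxels")
    z, y, x = grid.coords()
    half_extent = [c[-1] - c[0] for c in (z, y, x)]
    if diameter_um > min(half_extent):
        raise ValueError("bead does not fit inside the grid")
    if eps_mean is None:
        if n_bead is None:
            raise ValueError("provide n_bead or eps_mean")
        eps_mean = float(n_bead) ** 2
    _warn_regime(eps_mean - grid.eps_rm, delta_eps)

    R = diameter_um / 2.0
    dist = np.sqrt(
        (z[:, None, None] - center_um[0]) ** 2
        + (y[None, :, None] - center_um[1]) ** 2
        + (x[None, None, :] - center_um[2]) ** 2
    )
    if antialias:
        edge = min(grid.spacing)
        frac = np.clip((R - dist) / edge + 0.5, 0.0, 1.0)
    else:
        frac = (dist <= R).astype(float)
    eps = grid.eps_rm + (eps_mean - grid.eps_rm) * frac
    de = delta_eps * frac
    omega = np.full(grid.shape, axis[0])
    theta = np.full(grid.shape, axis[1])
    theta = np.where(frac > 0, theta, np.pi / 2.0)
    omega = np.where(frac > 0, omega, 0.0)
    return UniaxialField(eps, de, omega, theta)


def tube_phantom(
    grid: GridSpec,
    radius_um: float,
    shell_thickness_um: float,
    lipid_delta_eps: float = 0.01,
    shell_eps_contrast: float = 0.02,
    axis: str = "z",
) -> UniaxialField:
    """Hollow tube whose shell is positive uniaxial along the surface normal.

    Models a membrane-like shell: every shell voxel's symmetry axis is the
    local radial direction (perpendicular to the tube axis); lumen and
    exterior are isotropic at the medium permittivity.
    """
    if axis not in ("z", "y", "x"):
        raise ValueError("axis must be one of 'z', 'y', 'x'")
    z, y, x = grid.coords()
    Z = z[:, None, None]
    Y = y[None, :, None]
    X = x[None, None, :]
    if axis == "z":
        c1, c2 = Y, X
    elif axis == "y":
        c1, c2 = Z, X
    else:
        c1, c2 = Z, Y
    rho = np.sqrt(c1**2 + c2**2) * np.ones(grid.shape)
    r_out = radius_um + shell_thickness_um / 2.0
    if r_out > min(abs(y[0]), abs(x[0])):
        raise ValueError("tube shell does not fit inside the grid")
    shell = np.abs(rho - radius_um) <= shell_thickness_um / 2.0

    # unit surface normal expressed in (x, y, z) components, then converted
    # to (omega, theta); the UniaxialField constructor canonicalizes ranges
    safe_rho = np.maximum(rho, 1e-12)
    n1 = c1 / safe_rho * np.ones(grid.shape)
    n2 = c2 / safe_rho * np.ones(grid.shape)
    if axis == "z":      # (c1, c2) = (Y, X): normal = (X, Y, 0)
        ax_x, ax_y, ax_z = n2, n1, np.zeros(grid.shape)
    elif axis == "y":    # (c1, c2) = (Z, X): normal = (X, 0, Z)
        ax_x, ax_y, ax_z = n2, np.zeros(grid.shape), n1
    else:                # (c1, c2) = (Z, Y): normal = (0, Y, Z)
        ax_x, ax_y, ax_z = np.zeros(grid.shape), n2, n1
    theta = np.arccos(np.clip(ax_z, -1.0, 1.0))
    omega = np.arctan2(ax_y, ax_x)

    eps = np.where(shell, grid.eps_rm + shell_eps_contrast, grid.eps_rm)
    de = np.where(shell, abs(lipid_delta_eps), 0.0)
    om = np.where(shell, omega, 0.0)
    th = np.where(shell, theta, np.pi / 2.0)
    return UniaxialField(eps, de, om, th)
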