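"""Polarization-camera instrument model and Stokes preprocessing.

Raw four-analyzer intensities are mapped to (S0, S1, S2) through the
instrument matrix, corrected against an empty-field acquisition, and
DC-normalized into the S' volumes consumed by the inverse solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_sim import StokesData

__all__ = [
    "RawAcquisition",
    "InstrumentMatrix",
    "instrument_matrix",
    "stokes_to_intensities",
    "intensities_to_stokes",
    "background_correct",
    "normalize_dc",
]


@dataclass
class RawAcquisition:
    """Raw intensities I[alpha, c, z, y, x] with c the analyzer channel."""

    intensities: np.ndarray
    labels: list[str]
    is_background: bool = False

    def __post_init__(self) -> None:
        I = np.asarray(self.intensities, dtype=float)
        if I.ndim != 5:
            raise ValueError("intensities must be 5D (pattern, channel, z, y, x)")
        if I.shape[1] != 4:
            raise ValueError(
                f"expected 4 analyzer channels, got {I.shape[1]}; layout is "
                "(pattern, channel, z, y, x)"
            )
        if np.any(I < 0):
            raise ValueError("intensities must be non-negative")
        if len(self.labels) != I.shape[0]:
            raise ValueError("one pattern label per pattern required")
        self.intensities = I


@dataclass(frozen=True)
class InstrumentMatrix:
    """4x3 map from (S0, S1, S2) to the four analyzer intensities."""

    A: np.ndarray
    analyzer_angles: tuple[float, ...]

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.shape != (4, 3):
            raise ValueError("instrument matrix must be 4x3")
        if np.linalg.matrix_rank(A) < 3:
            raise ValueError("instrument matrix is rank deficient (< 3)")
        object.__setattr__(self, "A", A)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.A))


def instrument_matrix(
    analyzer_angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
) -> InstrumentMatrix:
    """Ideal Malus-law instrument matrix: rows 0.5 [1, cos 2phi, sin 2phi]."""
    if len(analyzer_angles) != 4:
        raise ValueError("exactly four analyzer angles required")
    phi = np.radians(np.asarray(analyzer_angles, dtype=float))
    A = 0.5 * np.stack([np.ones(4), np.cos(2 * phi), np.sin(2 * phi)], axis=1)
    try:
        return InstrumentMatrix(A, tuple(float(a) for a in analyzer_angles))
    except ValueError as err:
        raise ValueError(
            f"analyzer angles {analyzer_angles} give a singular instrument matrix"
        ) from err


def stokes_to_intensities(
    stokes: StokesData, A: InstrumentMatrix, labels_background: bool = False
) -> RawAcquisition:
    """Simulate the four analyzer intensities from (S0, S1, S2) volumes."""
    S = stokes.S[:, :3]
    I = np.einsum("cm,am...->ac...", A.A, S)
    I = np.clip(I, 0.0, None)  # Malus model cannot produce negative counts
    return RawAcquisition(I, list(stokes.labels), is_background=labels_background)


def intensities_to_stokes(raw: RawAcquisition, A: InstrumentMatrix) -> StokesData:
    """Per-voxel least-squares inversion of the instrument matrix.

    Exact when the four intensities are consistent; otherwise returns the
    minimizer of the four-channel residual (normal equations).
    """
    if A.condition_number > 1e8:
        raise ValueError(
            f"instrument matrix nearly singular (cond={A.condition_number:.3g})"
        )
    pinv = np.linalg.pinv(A.A)
    S = np.einsum("mc,ac...->am...", pinv, raw.intensities)
    return StokesData(S, list(raw.labels))


def background_correct(s_sample: StokesData, s_bg: StokesData) -> StokesData:
    """Normalized subtraction of the empty-field polarization state.

    ``S0 -> S0/S0_bg``, ``S1/S0 -> S1/S0 - S1_bg/S0_bg`` (same for S2).  The
    background broadcasts plane-wise over z.  Invariant to a common gain on
    sample and background.
    """
    S = s_sample.S
    B = s_bg.S
    if B.shape[0] != S.shape[0]:
        raise ValueError("background pattern count does not match sample")
    if np.any(B[:, 0] <= 0):
        raise ValueError("background S0 must be strictly positive")
    b0 = B[:, 0]
    s0 = S[:, 0]
    if np.any(s0 <= 0):
        raise ValueError("sample S0 must be strictly positive for ratio correction")
    out = np.empty((S.shape[0], 3) + S.shape[2:], dtype=float)
    out[:, 0] = s0 / b0
    out[:, 1] = S[:, 1] / s0 - B[:, 1] / b0
    out[:, 2] = S[:, 2] / s0 - B[:, 2] / b0
    return StokesData(out, list(s_sample.labels))


def normalize_dc(s: StokesData) -> StokesData:
    """DC-normalize into S': subtract/scale by the per-pattern mean of S0.

    ``S0' = (S0 - mean S0)/mean S0``; ``S1' = S1 / mean S0`` (same for S2),
    the spatial mean taken per pattern over the whole volume.  Invariant to
    exposure scaling.
    """
    S = s.S
    vol_axes = tuple(range(1, S.ndim - 1))
    m0 = S[:, 0].mean(axis=vol_axes, keepdims=True)
    if np.any(m0 <= 0):
        raise ValueError("mean S0 must be positive per pattern")
    out = np.empty((S.shape[0], 3) + S.shape[2:], dtype=float)
    out[:, 0] = (S[:, 0] - m0) / m0
    out[:, 1] = S[:, 1] / m0
    out[:, 2] = S[:, 2] / m0
    return StokesData(out, list(s.labels))
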