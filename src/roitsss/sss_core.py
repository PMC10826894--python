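"""Signal space separation (SSS) core: basis construction, moment estimation,
and inside/outside field reconstruction.

An N-channel MEG measurement b is modelled as a truncated multipole expansion

    b = S_in x_in + S_out x_out = b_in + b_out,

where the columns of S_in are the sensor-space fields of the interior
harmonic terms (sources inside the sensor array; potential falling off as
r^-(l+1)) and the columns of S_out those of the exterior terms (potential
growing as r^l).  Moments are estimated per sample by a regularised
pseudoinverse of the concatenated basis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._harmonics import harmonic_field_basis, lm_ordering

logger = logging.getLogger(__name__)

__all__ = [
    "SensorArray",
    "SSSConfig",
    "SSSBasis",
    "MultipoleMoments",
    "MEGRecording",
    "basis_dimension",
    "build_sss_basis",
    "estimate_moments",
    "reconstruct_components",
]


@dataclass
class SensorArray:
    """Point-magnetometer sensor geometry in the head frame (meters)."""

    positions: np.ndarray   # (N, 3)
    orientations: np.ndarray  # (N, 3) unit vectors
    names: list[str] = field(default_factory=list)
    sensor_model: str = "point_magnetometer"

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if self.positions.shape != self.orientations.shape or self.positions.shape[1] != 3:
            raise ValueError("positions and orientations must both be (N, 3)")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sensor orientations must be unit vectors (|n| = 1 ± 1e-9)")
        if not self.names:
            self.names = [f"MEG{i:04d}" for i in range(len(self.positions))]
        if len(self.names) != len(self.positions):
            raise ValueError("channel-name count does not match sensor count")
        if self.sensor_model != "point_magnetometer":
            raise ValueError(f"unsupported sensor model {self.sensor_model!r}")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


@dataclass
class SSSConfig:
    """Expansion origin, truncation orders, and pseudoinverse regularisation.

    L_in=8 and L_out=6 are the standard prespecified truncation orders.
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    L_in: int = 8
    L_out: int = 6
    pinv_cond: float = 1e-8
    scale_radius: float | None = None  # default: median sensor distance from origin

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.L_in < 1 or self.L_out < 1:
            raise ValueError("L_in and L_out must be >= 1")
        if not self.pinv_cond > 0:
            raise ValueError("pinv_cond must be > 0")


@dataclass
class SSSBasis:
    S_in: np.ndarray   # (N, D_in)
    S_out: np.ndarray  # (N, D_out)
    ordering_in: list[tuple[int, int]]
    ordering_out: list[tuple[int, int]]
    origin: np.ndarray
    scale_radius: float

    def __post_init__(self):
        if self.S_in.shape[1] != len(self.ordering_in):
            raise ValueError("S_in column count does not match (l, m) ordering")
        if self.S_out.shape[1] != len(self.ordering_out):
            raise ValueError("S_out column count does not match (l, m) ordering")

    @property
    def n_channels(self) -> int:
        return self.S_in.shape[0]

    @property
    def L_in(self) -> int:
        return self.ordering_in[-1][0]

    @property
    def l_in(self) -> np.ndarray:
        """Harmonic degree of each interior column."""
        return np.array([l for l, _ in self.ordering_in])


@dataclass
class MultipoleMoments:
    """Per-sample interior/exterior multipole moments (D, T)."""

    x_in: np.ndarray
    x_out: np.ndarray

    def __post_init__(self):
        self.x_in = np.atleast_2d(np.asarray(self.x_in, dtype=float))
        self.x_out = np.atleast_2d(np.asarray(self.x_out, dtype=float))
        if self.x_in.shape[1] != self.x_out.shape[1]:
            raise ValueError("x_in and x_out must share the sample dimension")


@dataclass
class MEGRecording:
    """Channels x samples data (tesla) with sampling rate and channel names."""

    data: np.ndarray
    sfreq: float
    names: list[str] = field(default_factory=list)
    events: np.ndarray | None = None  # event onsets, seconds

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if not self.sfreq > 0:
            raise ValueError("sfreq must be > 0")
        if not self.names:
            self.names = [f"MEG{i:04d}" for i in range(self.data.shape[0])]
        if len(self.names) != self.data.shape[0]:
            raise ValueError("channel-name count does not match data rows")
        if self.events is not None:
            self.events = np.asarray(self.events, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq


def basis_dimension(L: int) -> int:
    """Number of harmonic terms up to degree L: (L+1)^2 - 1.

    Equals the sum of the odd numbers 3, 5, ..., 2L+1 (one (2l+1)-sized
    shell of m-orders per degree l).
    """
    if not isinstance(L, (int, np.integer)) or L < 1:
        raise ValueError(f"L must be a positive integer, got {L!r}")
    return (L + 1) ** 2 - 1


def build_sss_basis(sensors: SensorArray, config: SSSConfig) -> SSSBasis:
    """Build the interior/exterior SSS design matrices for a sensor array.

    Each column is the field of one harmonic term projected onto each
    sensor's orientation (point-magnetometer model); deterministic in the
    geometry alone.
    """
    rel = sensors.positions - config.origin
    radii = np.linalg.norm(rel, axis=1)
    if np.any(radii <= 0):
        raise ValueError("sensor located at the SSS expansion origin")
    rho = config.scale_radius if config.scale_radius is not None else float(np.median(radii))

    n = sensors.orientations
    F_in = harmonic_field_basis(config.L_in, rel, "interior", rho)
    F_out = harmonic_field_basis(config.L_out, rel, "exterior", rho)
    S_in = np.einsum("pdk,pk->pd", F_in, n)
    S_out = np.einsum("pdk,pk->pd", F_out, n)

    D_total = S_in.shape[1] + S_out.shape[1]
    if sensors.n_channels < D_total:
        warnings.warn(
            f"{sensors.n_channels} channels < {D_total} basis columns: "
            "the joint basis is rank deficient and moments are not unique",
            RuntimeWarning,
        )
    return SSSBasis(
        S_in=S_in,
        S_out=S_out,
        ordering_in=lm_ordering(config.L_in),
        ordering_out=lm_ordering(config.L_out),
        origin=config.origin.copy(),
        scale_radius=rho,
    )


def _regularised_pinv(S: np.ndarray, pinv_cond: float) -> tuple[np.ndarray, int]:
    """SVD-truncated pseudoinverse; returns (S^+, number of discarded values)."""
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    keep = s > pinv_cond * s[0]
    n_discard = int(np.sum(~keep))
    if n_discard:
        logger.info(
            "pseudoinverse truncated %d singular values below %.3g (smallest kept %.3g)",
            n_discard, pinv_cond * s[0], s[keep][-1],
        )
    inv_s = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    return (Vt.T * inv_s) @ U.T, n_discard


def moment_projector(basis: SSSBasis, pinv_cond: float = 1e-8) -> np.ndarray:
    """(D_in + D_out) x N matrix mapping sensor data to multipole moments."""
    S = np.hstack([basis.S_in, basis.S_out])
    pinv, _ = _regularised_pinv(S, pinv_cond)
    return pinv


def estimate_moments(
    b: MEGRecording | np.ndarray, basis: SSSBasis, pinv_cond: float = 1e-8
) -> MultipoleMoments:
    """Least-squares multipole moments per sample, x_hat = S^+ b."""
    data = b.data if isinstance(b, MEGRecording) else np.atleast_2d(np.asarray(b, dtype=float))
    if data.shape[0] != basis.n_channels:
        raise ValueError(
            f"channel mismatch: data has {data.shape[0]} rows, basis expects {basis.n_channels}"
        )
    pinv = moment_projector(basis, pinv_cond)
    x = pinv @ data
    D_in = basis.S_in.shape[1]
    return MultipoleMoments(x_in=x[:D_in], x_out=x[D_in:])


def reconstruct_components(
    moments: MultipoleMoments, basis: SSSBasis, sfreq: float = 1.0
) -> tuple[MEGRecording, MEGRecording]:
    """Reconstruct the inside/outside sensor-space fields from moments."""
    if moments.x_in.shape[0] != basis.S_in.shape[1]:
        raise ValueError("x_in length does not match interior basis")
    if moments.x_out.shape[0] != basis.S_out.shape[1]:
        raise ValueError("x_out length does not match exterior basis")
    b_in = basis.S_in @ moments.x_in
    b_out = basis.S_out @ moments.x_out
    return (
        MEGRecording(data=b_in, sfreq=sfreq),
        MEGRecording(data=b_out, sfreq=sfreq),
    )
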