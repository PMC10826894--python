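"""Per-degree signal-power functions and the ROI radius / truncation-order
sweep.

The per-degree power of a source distribution is realised numerically:
forward fields of the sources are sampled on a dense ideal sensor shell
(Fibonacci layout), projected onto the interior SSS basis, and the field
power of each degree-l block accumulated.  The ROI-modified power function
scales each degree's amplitude by the diagonal ROI gain before squaring.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field

import numpy as np

from .roi_filter import CuboidROI, g_roi_cuboid, g_roi_sphere
from .sss_core import SensorArray, SSSConfig, build_sss_basis
from .synthetic_phantom import dipole_forward, fibonacci_sphere_array

__all__ = [
    "PowerSweepConfig",
    "random_shell_dipoles",
    "per_l_power",
    "roi_power_function",
    "run_radius_sweep",
    "write_sweep_csv",
]


@dataclass
class PowerSweepConfig:
    """Configuration of the ROI-size sweep: 100 randomly oriented dipoles on
    a 0.04 m shell, sensors at R = 0.08 m."""

    n_sources: int = 100
    source_radius: float = 0.04
    R: float = 0.08
    roi_radii: list = dc_field(
        default_factory=lambda: [0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07]
    )
    L_max: int = 8
    roi_shape: str = "sphere"
    n_shell_sensors: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not self.source_radius < self.R:
            raise ValueError("source radius must be < R")
        if any(r > self.R for r in self.roi_radii):
            raise ValueError("all ROI radii must be <= R")
        if self.roi_shape not in ("sphere", "cube"):
            raise ValueError("roi_shape must be 'sphere' or 'cube'")


def random_shell_dipoles(
    n: int, radius: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform positions on a shell with uniformly random orientations.

    Orientations are drawn uniformly on the unit sphere; silent radial parts
    are discarded automatically by the conducting-sphere forward model.
    """
    pos = rng.normal(size=(n, 3))
    pos *= radius / np.linalg.norm(pos, axis=1, keepdims=True)
    ori = rng.normal(size=(n, 3))
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    return pos, ori


def _forward_matrix(
    positions: np.ndarray, orientations: np.ndarray, shell: SensorArray
) -> np.ndarray:
    """(N_sensors, n_sources) fields of unit-moment dipoles."""
    cols = [
        dipole_forward(p, q * 1e-8, shell) for p, q in zip(positions, orientations)
    ]
    return np.stack(cols, axis=1)


def per_l_power(
    positions: np.ndarray,
    orientations: np.ndarray,
    R: float,
    L_max: int = 8,
    n_shell_sensors: int = 2000,
) -> np.ndarray:
    """Summed field power per harmonic degree l = 1..L_max of a dipole set.

    Each dipole contributes incoherently (powers add).  Sources must lie
    strictly inside the shell radius R.
    """
    positions = np.atleast_2d(positions)
    orientations = np.atleast_2d(orientations)
    if np.any(np.linalg.norm(positions, axis=1) >= R):
        raise ValueError("all sources must lie strictly inside the shell radius R")
    shell = fibonacci_sphere_array(n_shell_sensors, R)
    cfg = SSSConfig(L_in=L_max, L_out=1)
    basis = build_sss_basis(shell, cfg)
    # Interior-only projection: no exterior sources in this idealised setup.
    pinv_in = np.linalg.pinv(basis.S_in, rcond=1e-10)
    B = _forward_matrix(positions, orientations, shell)
    X = pinv_in @ B
    ls = basis.l_in
    power = np.empty(L_max)
    for l in range(1, L_max + 1):
        block = ls == l
        power[l - 1] = float(np.sum((basis.S_in[:, block] @ X[block]) ** 2))
    return power


def roi_power_function(
    positions: np.ndarray,
    orientations: np.ndarray,
    roi,
    R: float,
    L_max: int = 8,
    n_shell_sensors: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-degree power with amplitudes scaled by the ROI gain, plus the
    cumulative power over l.

    ``roi`` is a SphericalROI-like radius (float), a DiagonalFilter, or a
    CuboidROI; gains are evaluated for an origin-centred ROI against the
    shell radius R.
    """
    base = per_l_power(positions, orientations, R, L_max, n_shell_sensors)
    if isinstance(roi, CuboidROI):
        filt = g_roi_cuboid(roi, np.zeros(3), R, L_max)
    elif np.isscalar(roi):
        filt = g_roi_sphere(float(roi), R, L_max)
    else:
        filt = roi
    gains_l = np.array([filt.diag[filt.l_index == l][0] for l in range(1, L_max + 1)])
    scaled = gains_l**2 * base
    return scaled, np.cumsum(scaled)


def run_radius_sweep(cfg: PowerSweepConfig) -> list[dict]:
    """ROI-size sweep: per-degree and cumulative recovered power for each
    ROI size, for a sphere or a cube whose body diagonal matches the sphere
    diameter.  Deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    pos, ori = random_shell_dipoles(cfg.n_sources, cfg.source_radius, rng)
    total = per_l_power(pos, ori, cfg.R, cfg.L_max, cfg.n_shell_sensors)
    rows = []
    for r in cfg.roi_radii:
        if cfg.roi_shape == "sphere":
            roi = float(r)
        else:
            side = 2.0 * r / np.sqrt(3.0)  # body diagonal = sphere diameter
            roi = CuboidROI(center=np.zeros(3), sides=np.full(3, side))
        scaled, cum = roi_power_function(
            pos, ori, roi, cfg.R, cfg.L_max, cfg.n_shell_sensors
        )
        for l in range(1, cfg.L_max + 1):
            rows.append(
                {
                    "roi_size": float(r),
                    "shape": cfg.roi_shape,
                    "l": l,
                    "power": float(scaled[l - 1]),
                    "cumulative_power": float(cum[l - 1]),
                    "total_power_l": float(total[l - 1]),
                }
            )
    return rows


def write_sweep_csv(rows: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
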