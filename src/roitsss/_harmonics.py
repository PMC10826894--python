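"""Real spherical harmonics and harmonic-potential field basis functions.

Convention
----------
Fully normalised (orthonormal) real spherical harmonics built from the
complex orthonormal set Y_l^m (Condon–Shortley phase):

    Y_{l,m}  = sqrt(2) (-1)^m Re(Y_l^m)      m > 0
    Y_{l,0}  = Y_l^0
    Y_{l,-m} = sqrt(2) (-1)^m Im(Y_l^m)      m > 0

Any consistent normalisation rescales multipole moments but leaves
reconstructed fields unchanged; the invariance is exercised in the tests.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y_all

# Polar angles are clamped away from the coordinate poles where the
# phi-derivative term 1/sin(theta) is formally 0/0; the induced evaluation
# error is O(eps^2).
_POLE_EPS = 1e-10


def lm_ordering(L: int) -> list[tuple[int, int]]:
    """Column ordering of the harmonic basis: l = 1..L outer, m = -l..l inner."""
    if L < 1:
        raise ValueError(f"harmonic degree L must be >= 1, got {L}")
    return [(l, m) for l in range(1, L + 1) for m in range(-l, l + 1)]


def cartesian_to_spherical(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(P, 3) cartesian points -> radius, polar angle theta, azimuth phi."""
    points = np.asarray(points, dtype=float)
    r = np.linalg.norm(points, axis=-1)
    if np.any(r <= 0):
        raise ValueError("points at the expansion origin have undefined angles")
    theta = np.arccos(np.clip(points[..., 2] / r, -1.0, 1.0))
    phi = np.arctan2(points[..., 1], points[..., 0])
    return r, theta, phi


def real_harmonics_with_gradients(
    L: int, theta: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate real Y_{l,m} and angular derivatives for l = 1..L.

    Returns
    -------
    Y, dY_dtheta, dY_dphi : ndarray, shape (P, D) with D = (L+1)**2 - 1,
        columns in :func:`lm_ordering` order.
    """
    theta = np.clip(np.asarray(theta, dtype=float), _POLE_EPS, np.pi - _POLE_EPS)
    phi = np.asarray(phi, dtype=float)
    yc, dyc = sph_harm_y_all(L, L, theta, phi, diff_n=1)

    P = theta.shape[0]
    D = (L + 1) ** 2 - 1
    Y = np.empty((P, D))
    dYt = np.empty((P, D))
    dYp = np.empty((P, D))
    sqrt2 = np.sqrt(2.0)
    for j, (l, m) in enumerate(lm_ordering(L)):
        if m == 0:
            Y[:, j] = yc[l, 0].real
            dYt[:, j] = dyc[l, 0, :, 0].real
            dYp[:, j] = dyc[l, 0, :, 1].real
        elif m > 0:
            s = sqrt2 * (-1.0) ** m
            Y[:, j] = s * yc[l, m].real
            dYt[:, j] = s * dyc[l, m, :, 0].real
            dYp[:, j] = s * dyc[l, m, :, 1].real
        else:
            s = sqrt2 * (-1.0) ** (-m)
            Y[:, j] = s * yc[l, -m].imag
            dYt[:, j] = s * dyc[l, -m, :, 0].imag
            dYp[:, j] = s * dyc[l, -m, :, 1].imag
    return Y, dYt, dYp


def _spherical_unit_vectors(theta: np.ndarray, phi: np.ndarray):
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    r_hat = np.stack([st * cp, st * sp, ct], axis=-1)
    t_hat = np.stack([ct * cp, ct * sp, -st], axis=-1)
    p_hat = np.stack([-sp, cp, np.zeros_like(phi)], axis=-1)
    return r_hat, t_hat, p_hat


def harmonic_field_basis(
    L: int,
    points: np.ndarray,
    kind: str,
    scale_radius: float,
) -> np.ndarray:
    """Vector fields -grad(V_lm) of the harmonic potentials at ``points``.

    kind='interior': V_lm = scale_radius * (scale_radius / r)**(l+1) * Y_lm,
    the potential of sources near the origin, evaluated outside them.
    kind='exterior': V_lm = scale_radius * (r / scale_radius)**l * Y_lm,
    the potential of distant sources, evaluated inside them.

    The scale_radius factors make the columns order unity where
    r ~ scale_radius; multipole moments are then expressed in tesla at the
    scale radius.

    Returns (P, D, 3) cartesian field vectors.
    """
    points = np.asarray(points, dtype=float)
    r, theta, phi = cartesian_to_spherical(points)
    theta = np.clip(theta, _POLE_EPS, np.pi - _POLE_EPS)
    Y, dYt, dYp = real_harmonics_with_gradients(L, theta, phi)
    r_hat, t_hat, p_hat = _spherical_unit_vectors(theta, phi)

    D = (L + 1) ** 2 - 1
    out = np.empty((points.shape[0], D, 3))
    inv_sin = 1.0 / np.sin(theta)
    ls = np.array([l for l, _ in lm_ordering(L)])
    rho = float(scale_radius)
    for j, l in enumerate(ls):
        if kind == "interior":
            f = rho * (rho / r) ** (l + 1)      # potential radial factor
            df = -(l + 1) * f / r               # d/dr
        elif kind == "exterior":
            f = rho * (r / rho) ** l
            df = l * f / r
        else:
            raise ValueError(f"unknown basis kind {kind!r}")
        # -grad of f(r) Y(theta, phi)
        vec = (
            -df[:, None] * Y[:, j, None] * r_hat
            - (f / r)[:, None] * dYt[:, j, None] * t_hat
            - (f / r * inv_sin)[:, None] * dYp[:, j, None] * p_hat
        )
        out[:, j, :] = vec
    return out
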