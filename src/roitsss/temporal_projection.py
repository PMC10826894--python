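"""Temporal-subspace intersection and projection.

Given the sensor-space time series of two spatial subspaces (ROI vs.
non-ROI, or inside vs. outside), the temporal bases of their row spaces are
orthonormalised and the principal angles between them obtained from the
singular values of the cross-product of the two bases.  Time courses whose
canonical correlation (singular value) reaches the threshold are treated as
zero-lag-correlated leakage and projected out of the first subspace.

Energy floor
------------
The ROI and non-ROI subspaces are diagonal reweightings of the same
interior moment time series, so their *exact* row spaces coincide; the
intersection is only meaningful over the energetically significant
components of each subspace.  Each temporal basis therefore retains only
components whose singular value exceeds ``rank_rtol`` times the largest
singular value across both subspaces (default 1e-3, i.e. -60 dB).  A deep
source that leaks into the non-ROI subspace at the ~1e-4 level falls below
this floor and is preserved, while high-amplitude interference remains
above it in both subspaces and is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TemporalProjectionConfig",
    "CommonSubspace",
    "common_temporal_subspace",
    "project_out",
]


@dataclass
class TemporalProjectionConfig:
    correlation_threshold: float = 0.98
    window_seconds: float | None = None  # None: whole recording, single window
    rank_rtol: float = 1e-3  # energy floor relative to the joint largest sv
    # A correlated component is only removed when its amplitude in the
    # reference subspace is a substantial fraction of its amplitude in the
    # cleaned subspace: content that truly originates outside the ROI is
    # strong in the reference, whereas the ROI signal's own leakage appears
    # there only at the percent level and must be preserved.
    leakage_ratio_min: float = 0.1
    normalisation: str = "row_orthonormalise"

    def __post_init__(self):
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in (0, 1]")
        if not 0 < self.rank_rtol < 1:
            raise ValueError("rank_rtol must be in (0, 1)")
        if not 0 <= self.leakage_ratio_min < 1:
            raise ValueError("leakage_ratio_min must be in [0, 1)")
        if self.normalisation != "row_orthonormalise":
            raise ValueError(f"unknown normalisation {self.normalisation!r}")


@dataclass
class CommonSubspace:
    """Orthonormal common time courses (T, k) and all canonical correlations."""

    time_courses: np.ndarray
    singular_values: np.ndarray

    @property
    def n_components(self) -> int:
        return self.time_courses.shape[1]


def common_temporal_subspace(
    B_roi: np.ndarray,
    B_not_roi: np.ndarray,
    cfg: TemporalProjectionConfig | None = None,
    max_rank: int | None = None,
) -> CommonSubspace:
    """Time courses shared (at zero lag) between two sensor-space subspaces.

    Both matrices are channels x time with equal sample counts.  ``max_rank``
    caps the temporal rank of each basis (typically the interior basis
    dimension D_in).
    """
    cfg = cfg or TemporalProjectionConfig()
    B_roi = np.atleast_2d(np.asarray(B_roi, dtype=float))
    B_not_roi = np.atleast_2d(np.asarray(B_not_roi, dtype=float))
    if B_roi.shape[1] != B_not_roi.shape[1]:
        raise ValueError("subspace matrices must have equal sample counts")
    T = B_roi.shape[1]
    rank_bound = min(min(B_roi.shape), min(B_not_roi.shape))
    if max_rank is not None:
        rank_bound = min(rank_bound, max_rank)
    if T < 10 * rank_bound:
        raise ValueError(
            f"window of {T} samples is too short for a rank-{rank_bound} temporal "
            f"basis; need at least {10 * rank_bound} samples"
        )
    _, s1, V1t = np.linalg.svd(B_roi, full_matrices=False)
    _, s2, V2t = np.linalg.svd(B_not_roi, full_matrices=False)
    scale = max(s1[0] if s1.size else 0.0, s2[0] if s2.size else 0.0)
    if scale == 0.0:
        return CommonSubspace(np.empty((T, 0)), np.empty(0))
    floor = cfg.rank_rtol * scale
    k1 = int(np.sum(s1 > floor))
    k2 = int(np.sum(s2 > floor))
    if max_rank is not None:
        k1, k2 = min(k1, max_rank), min(k2, max_rank)
    if k1 == 0 or k2 == 0:
        return CommonSubspace(np.empty((T, 0)), np.empty(0))
    V1, V2 = V1t[:k1].T, V2t[:k2].T
    P, s, _ = np.linalg.svd(V1.T @ V2, full_matrices=False)
    keep = s >= cfg.correlation_threshold
    if np.any(keep) and cfg.leakage_ratio_min > 0:
        U_cand = V1 @ P[:, keep]
        amp_roi = np.linalg.norm(B_roi @ U_cand, axis=0)
        amp_ref = np.linalg.norm(B_not_roi @ U_cand, axis=0)
        substantial = amp_ref >= cfg.leakage_ratio_min * np.maximum(amp_roi, 1e-300)
        idx = np.flatnonzero(keep)
        keep = np.zeros_like(keep)
        keep[idx[substantial]] = True
    U = V1 @ P[:, keep]
    # Re-orthonormalise to guard against accumulated rounding.
    if U.shape[1]:
        U, _ = np.linalg.qr(U)
    return CommonSubspace(time_courses=U, singular_values=s)


def project_out(B_roi: np.ndarray, common: CommonSubspace | np.ndarray) -> np.ndarray:
    """Remove the common time courses from B_roi: B (I - U U^T) over time."""
    B_roi = np.atleast_2d(np.asarray(B_roi, dtype=float))
    U = common.time_courses if isinstance(common, CommonSubspace) else np.asarray(common)
    if U.ndim == 1:
        U = U[:, None]
    if U.shape[1] == 0:
        return B_roi.copy()
    if U.shape[0] != B_roi.shape[1]:
        raise ValueError("time-course length does not match the data samples")
    gram = U.T @ U
    if not np.allclose(gram, np.eye(U.shape[1]), atol=1e-8):
        raise ValueError("common time courses must be orthonormal")
    return B_roi - (B_roi @ U) @ U.T
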