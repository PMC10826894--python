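"""End-to-end denoising pipelines (standard / tSSS / ROI-tSSS), leadfield
montage transform, HPI head-tracking correction, evoked-response epoching
and topography mean-squared error."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import firwin, oaconvolve

from .roi_filter import (
    CuboidROI,
    SphericalROI,
    effective_R,
    g_not_roi_cuboid,
    g_not_roi_sphere,
    g_roi_cuboid,
    g_roi_sphere,
    split_by_roi,
)
from .sss_core import (
    MEGRecording,
    SensorArray,
    SSSConfig,
    build_sss_basis,
    estimate_moments,
    moment_projector,
)
from .temporal_projection import (
    TemporalProjectionConfig,
    common_temporal_subspace,
    project_out,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DenoiseResult",
    "EvokedTopography",
    "standard",
    "tsss",
    "roi_tsss",
    "transform_leadfields",
    "hpi_track_correct",
    "epoch_average",
    "topography_mse",
]


@dataclass
class DenoiseResult:
    cleaned: MEGRecording
    spatial_operator: np.ndarray        # (N, N): raw data -> spatial-stage output
    removed_components: int
    singular_values: np.ndarray         # all canonical correlations
    log: dict = field(default_factory=dict)


@dataclass
class EvokedTopography:
    """Trial-averaged, baseline-corrected sensor topography over time."""

    data: np.ndarray       # (N, n_times)
    times: np.ndarray      # relative to event onset, seconds
    n_trials: int
    baseline: tuple

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("trial count must be > 0")


def _check_geometry(rec: MEGRecording, sensors: SensorArray):
    if rec.n_channels != sensors.n_channels:
        raise ValueError(
            f"recording has {rec.n_channels} channels but sensor array has "
            f"{sensors.n_channels}"
        )


def standard(rec: MEGRecording) -> DenoiseResult:
    """No denoising; identity spatial operator (control condition)."""
    return DenoiseResult(
        cleaned=MEGRecording(rec.data.copy(), rec.sfreq, list(rec.names), rec.events),
        spatial_operator=np.eye(rec.n_channels),
        removed_components=0,
        singular_values=np.empty(0),
        log={"method": "standard"},
    )


def _windows(n_samples: int, sfreq: float, window_seconds: float | None):
    if window_seconds is None:
        return [(0, n_samples)]
    w = int(round(window_seconds * sfreq))
    if w <= 0:
        raise ValueError("window_seconds must be positive")
    edges = list(range(0, n_samples, w))
    spans = [(e, min(e + w, n_samples)) for e in edges]
    # Merge a short tail into the previous window.
    if len(spans) > 1 and spans[-1][1] - spans[-1][0] < w // 2:
        spans[-2] = (spans[-2][0], spans[-1][1])
        spans.pop()
    return spans


def _temporal_stage(B_keep, B_other, tp_cfg, max_rank, sfreq):
    """Project common time courses out of B_keep, windowed if configured."""
    cleaned = np.empty_like(B_keep)
    svs = []
    removed = 0
    for a, b in _windows(B_keep.shape[1], sfreq, tp_cfg.window_seconds):
        try:
            common = common_temporal_subspace(
                B_keep[:, a:b], B_other[:, a:b], tp_cfg, max_rank=max_rank
            )
        except ValueError as err:
            raise ValueError(f"temporal-projection stage: {err}") from err
        cleaned[:, a:b] = project_out(B_keep[:, a:b], common)
        svs.append(common.singular_values)
        removed += common.n_components
    return cleaned, removed, np.concatenate(svs) if svs else np.empty(0)


def tsss(
    rec: MEGRecording,
    sensors: SensorArray,
    sss_cfg: SSSConfig | None = None,
    tp_cfg: TemporalProjectionConfig | None = None,
) -> DenoiseResult:
    """Spatiotemporal SSS: keep the inside component, remove time courses it
    shares (at zero lag) with the outside component."""
    sss_cfg = sss_cfg or SSSConfig()
    tp_cfg = tp_cfg or TemporalProjectionConfig()
    _check_geometry(rec, sensors)
    try:
        basis = build_sss_basis(sensors, sss_cfg)
        pinv = moment_projector(basis, sss_cfg.pinv_cond)
    except ValueError as err:
        raise ValueError(f"SSS basis stage: {err}") from err
    D_in = basis.S_in.shape[1]
    x = pinv @ rec.data
    B_in = basis.S_in @ x[:D_in]
    B_out = basis.S_out @ x[D_in:]
    cleaned, removed, svs = _temporal_stage(B_in, B_out, tp_cfg, D_in, rec.sfreq)
    op = basis.S_in @ pinv[:D_in]
    return DenoiseResult(
        cleaned=MEGRecording(cleaned, rec.sfreq, list(rec.names), rec.events),
        spatial_operator=op,
        removed_components=removed,
        singular_values=svs,
        log={"method": "tsss", "L_in": sss_cfg.L_in, "L_out": sss_cfg.L_out},
    )


def roi_tsss(
    rec: MEGRecording,
    sensors: SensorArray,
    roi: SphericalROI | CuboidROI,
    sss_cfg: SSSConfig | None = None,
    tp_cfg: TemporalProjectionConfig | None = None,
) -> DenoiseResult:
    """ROI-tSSS: split the inside component into ROI / non-ROI parts with the
    diagonal harmonic filters, then remove from the ROI part the time courses
    shared with the non-ROI part (zero-lag leakage)."""
    sss_cfg = sss_cfg or SSSConfig()
    tp_cfg = tp_cfg or TemporalProjectionConfig()
    _check_geometry(rec, sensors)
    try:
        basis = build_sss_basis(sensors, sss_cfg)
        pinv = moment_projector(basis, sss_cfg.pinv_cond)
    except ValueError as err:
        raise ValueError(f"SSS basis stage: {err}") from err
    array_radius = float(
        np.median(np.linalg.norm(sensors.positions - sss_cfg.origin, axis=1))
    )
    try:
        if isinstance(roi, SphericalROI):
            R = effective_R(roi.center, sss_cfg.origin, array_radius)
            g = g_roi_sphere(roi.radius, R, sss_cfg.L_in)
            g_not = g_not_roi_sphere(roi.radius, R, sss_cfg.L_in)
        else:
            g = g_roi_cuboid(roi, sss_cfg.origin, array_radius, sss_cfg.L_in)
            g_not = g_not_roi_cuboid(roi, sss_cfg.origin, array_radius, sss_cfg.L_in)
    except ValueError as err:
        raise ValueError(f"ROI filter stage: {err}") from err
    D_in = basis.S_in.shape[1]
    moments = estimate_moments(rec, basis, sss_cfg.pinv_cond)
    b_roi, b_not = split_by_roi(moments, (g, g_not), basis, rec.sfreq)
    # Leakage into the ROI can originate from the rest of the inner volume
    # or from exterior interference, so the temporal reference stacks the
    # non-ROI component with the SSS outside component.
    b_out = basis.S_out @ moments.x_out
    reference = np.vstack([b_not.data, b_out])
    cleaned, removed, svs = _temporal_stage(
        b_roi.data, reference, tp_cfg, D_in + basis.S_out.shape[1], rec.sfreq
    )
    op = basis.S_in @ (g.diag[:, None] * pinv[:D_in])
    return DenoiseResult(
        cleaned=MEGRecording(cleaned, rec.sfreq, list(rec.names), rec.events),
        spatial_operator=op,
        removed_components=removed,
        singular_values=svs,
        log={
            "method": "roi_tsss",
            "roi": type(roi).__name__,
            "effective_R": effective_R(roi.center, sss_cfg.origin, array_radius),
        },
    )


def transform_leadfields(leadfields: np.ndarray, spatial_operator: np.ndarray) -> np.ndarray:
    """Apply the spatial part of a denoiser to leadfields (N x K per source),
    preserving the sensor-to-source mapping for downstream source analysis."""
    leadfields = np.asarray(leadfields, dtype=float)
    if leadfields.shape[0] != spatial_operator.shape[1]:
        raise ValueError(
            f"leadfield channel dimension {leadfields.shape[0]} does not match "
            f"operator size {spatial_operator.shape[1]}"
        )
    return spatial_operator @ leadfields


def hpi_track_correct(
    coil_positions: np.ndarray, tolerance_mm: float = 2.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Robust continuous head tracking from three HPI coil trajectories.

    The pairwise distances between the coils are constant for a rigid head;
    samples where any pairwise distance deviates from its run median by more
    than the tolerance are flagged as tracking losses and bridged by linear
    interpolation.  Returns (corrected (3, T, 3), flagged (T,) bool, robust
    head position estimate (3, 3) = time average of the corrected coils).
    """
    pos = np.asarray(coil_positions, dtype=float)
    if pos.ndim != 3 or pos.shape[0] != 3 or pos.shape[2] != 3:
        raise ValueError("coil_positions must be (3 coils, T, 3 coordinates)")
    T = pos.shape[1]
    tol = tolerance_mm * 1e-3
    pairs = [(0, 1), (0, 2), (1, 2)]
    flagged = np.zeros(T, dtype=bool)
    for i, j in pairs:
        d = np.linalg.norm(pos[i] - pos[j], axis=1)
        flagged |= np.abs(d - np.median(d)) > tol
    if flagged.all():
        raise ValueError("head tracking lost for the entire run")
    if flagged.mean() > 0.5:
        warnings.warn(
            f"{100 * flagged.mean():.0f}% of samples flagged: head position "
            "estimate is unreliable",
            RuntimeWarning,
        )
    corrected = pos.copy()
    good = np.flatnonzero(~flagged)
    bad = np.flatnonzero(flagged)
    if bad.size:
        for c in range(3):
            for k in range(3):
                corrected[c, bad, k] = np.interp(bad, good, pos[c, good, k])
    return corrected, flagged, corrected.mean(axis=1)


def _highpass(data: np.ndarray, sfreq: float, cutoff: float) -> np.ndarray:
    """Zero-phase FIR high-pass (Hamming, 2 Hz transition band)."""
    if cutoff <= 0:
        return data
    numtaps = int(3.3 * sfreq / 2.0)
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    taps = firwin(numtaps, cutoff, fs=sfreq, pass_zero=False, window="hamming")
    return oaconvolve(data, taps[None, :], mode="same", axes=1)


def epoch_average(
    rec: MEGRecording,
    events: np.ndarray | None = None,
    window: tuple = (-0.05, 0.05),
    baseline: tuple = (-0.05, -0.03),
    highpass: float = 5.0,
) -> EvokedTopography:
    """High-pass, epoch around events, baseline-correct, and average trials."""
    events = rec.events if events is None else np.asarray(events, dtype=float)
    if events is None or events.size == 0:
        raise ValueError("no events supplied for epoching")
    data = _highpass(rec.data, rec.sfreq, highpass)
    i0 = int(np.round(window[0] * rec.sfreq))
    i1 = int(np.round(window[1] * rec.sfreq))
    n_t = i1 - i0 + 1
    samp = np.round(events * rec.sfreq).astype(int)
    valid = (samp + i0 >= 0) & (samp + i1 < rec.n_samples)
    samp = samp[valid]
    if samp.size == 0:
        raise ValueError("no events fall within the recording after windowing")
    idx = samp[:, None] + np.arange(i0, i1 + 1)[None, :]
    epochs = data[:, idx]                      # (N, n_trials, n_t)
    times = np.arange(i0, i1 + 1) / rec.sfreq
    bmask = (times >= baseline[0]) & (times <= baseline[1])
    if bmask.any():
        epochs = epochs - epochs[:, :, bmask].mean(axis=2, keepdims=True)
    avg = epochs.mean(axis=1)
    return EvokedTopography(
        data=avg, times=times, n_trials=int(samp.size), baseline=tuple(baseline)
    )


def topography_mse(evoked_a: EvokedTopography, evoked_b: EvokedTopography) -> float:
    """Mean over channels and samples of the squared topography difference."""
    if evoked_a.data.shape != evoked_b.data.shape:
        raise ValueError("evoked topographies must have matching channels/samples")
    return float(np.mean((evoked_a.data - evoked_b.data) ** 2))
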