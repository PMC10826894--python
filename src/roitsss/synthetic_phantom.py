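"""Synthetic dry-bench phantom: a sinusoidal current dipole in a conducting
sphere plus DBS pulse-train, pulsation-movement and ferromagnetic-wire
artifacts, sampled by a helmet-like point-magnetometer array.

The simulator emulates a saline phantom experiment: a 27 Hz, 6.7 uA dipolar
source inside a 13 cm-inner-diameter conducting sphere, monopolar DBS pulse
trains (0/5/20/130 Hz, 60 us pulses) with inter-pulse ringing, a 60-per-
minute pulsation that vertically displaces the phantom (balloon inflation),
and ferromagnetic extension wires on the phantom surface whose
movement-stimulation interaction is a dominant artifact.  Movement effects
are modelled physically: a displaced source's field perturbation is
(dB/dz) * dz(t), a spatially distinct gradient topography built by finite
differences of the same forward model, so the per-source modulation depth
follows from the geometry (roughly 3/r per metre of displacement - a few
percent per millimetre for deep sources, 15-20 %/mm for the surface wires).
Everything is reproducible from an integer seed and returns its own ground
truth, so every downstream stage is testable without recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sss_core import MEGRecording, SensorArray

MU0_OVER_4PI = 1e-7  # T m / (A m)

__all__ = [
    "PhantomConfig",
    "PhantomGroundTruth",
    "helmet_sensor_array",
    "fibonacci_sphere_array",
    "dipole_forward",
    "magnetic_dipole_forward",
    "dbs_artifact",
    "movement_wire_artifact",
    "simulate_phantom_recording",
]


def _fibonacci_directions(n: int, z_min: float = -1.0, z_max: float = 1.0) -> np.ndarray:
    """Quasi-uniform unit vectors with z in [z_min, z_max] (never exactly polar)."""
    i = np.arange(n) + 0.5
    z = z_max - (z_max - z_min) * i / n
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * np.arange(n)
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), z], axis=1)


def helmet_sensor_array(
    n_sensors: int = 275,
    radius: float = 0.08,
    z_min: float = -0.45,
    n_reference: int = 29,
) -> SensorArray:
    """Helmet-like cap of point magnetometers plus reference layers.

    The primary cap covers the upper portion of an ellipsoid with
    equatorial radius ``radius`` and a 25% taller polar axis (default 275
    channels at 0.08 m).  Two layers of ``n_reference`` radially oriented
    reference magnetometers at 1.4x and 1.9x the array radius emulate the
    reference array of whole-head systems.  The radial diversity they add
    is essential: on a single shell, interior and exterior harmonics
    produce near-proportional fields and the inside/outside decomposition
    becomes numerically degenerate.
    """
    a, c = radius, 1.25 * radius
    dirs = _fibonacci_directions(n_sensors, z_min=z_min, z_max=1.0)
    scale = 1.0 / np.sqrt(
        (dirs[:, 0] ** 2 + dirs[:, 1] ** 2) / a**2 + dirs[:, 2] ** 2 / c**2
    )
    pos = [dirs * scale[:, None]]
    normals = dirs * scale[:, None] / np.array([a**2, a**2, c**2])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    ori = [normals]
    if n_reference > 0:
        for mult in (1.4, 1.9):
            rd = _fibonacci_directions(n_reference, z_min=-0.5, z_max=1.0)
            pos.append(mult * radius * rd)
            ori.append(rd)
    return SensorArray(positions=np.vstack(pos), orientations=np.vstack(ori))


def fibonacci_sphere_array(n_sensors: int = 2000, radius: float = 0.08) -> SensorArray:
    """Dense ideal full shell of radial point magnetometers."""
    dirs = _fibonacci_directions(n_sensors)
    return SensorArray(positions=radius * dirs, orientations=dirs)


def dipole_forward(
    position,
    moment,
    sensors: SensorArray,
    sphere_center=(0.0, 0.0, 0.0),
    sphere_radius: float | None = None,
) -> np.ndarray:
    """Field of a current dipole in a homogeneous conducting sphere (Sarvas).

    Returns the field projected on each sensor orientation (tesla per the
    moment's A m units).  Radial dipoles and dipoles at the sphere centre
    are magnetically silent.
    """
    r0 = np.asarray(position, dtype=float) - np.asarray(sphere_center, dtype=float)
    q = np.asarray(moment, dtype=float)
    if sphere_radius is not None and np.linalg.norm(r0) >= sphere_radius:
        raise ValueError("dipole must lie strictly inside the conducting sphere")
    r = sensors.positions - np.asarray(sphere_center, dtype=float)
    rn = np.linalg.norm(r, axis=1)
    if sphere_radius is not None and np.any(rn <= sphere_radius):
        raise ValueError("sensors must lie outside the conducting sphere")
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    adotr = np.einsum("ij,ij->i", a_vec, r)
    F = a * (rn * a + rn**2 - r0 @ r.T)
    gradF = (
        (a**2 / rn + adotr / a + 2 * a + 2 * rn)[:, None] * r
        - (a + 2 * rn + adotr / a)[:, None] * r0
    )
    qxr0 = np.cross(q, r0)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (
        F[:, None] * qxr0 - (r @ qxr0)[:, None] * gradF
    )
    return np.einsum("ij,ij->i", B, sensors.orientations)


def magnetic_dipole_forward(position, moment, sensors: SensorArray) -> np.ndarray:
    """Free-space magnetic point dipole (an exterior interference source)."""
    p = np.asarray(position, dtype=float)
    m = np.asarray(moment, dtype=float)
    d = sensors.positions - p
    dist = np.linalg.norm(d, axis=1)
    d_hat = d / dist[:, None]
    B = MU0_OVER_4PI / dist[:, None] ** 3 * (3 * (d_hat @ m)[:, None] * d_hat - m)
    return np.einsum("ij,ij->i", B, sensors.orientations)


@dataclass
class PhantomConfig:
    """Full parameterisation of the synthetic phantom experiment (SI units
    unless suffixed)."""

    sphere_radius: float = 0.065          # 13 cm inner diameter
    dipole_position: tuple = (0.0, 0.0, 0.04)
    dipole_orientation: tuple = (1.0, 0.0, 0.0)   # tangential
    dipole_amplitude_uA: float = 6.7
    dipole_length_m: float = 0.01         # effective current-dipole arm
    drive_frequency: float = 27.0
    dbs_frequency: float = 130.0          # one of {0, 5, 20, 130}
    pulse_width_us: float = 60.0
    dbs_relative_amplitude: float = 200.0  # DBS artifact RMS / clean dipole RMS
    ringing_frequency: float = 450.0
    ringing_decay_s: float = 2.0e-3
    ringing_relative_amplitude: float = 1.0
    electrode_position: tuple = (0.012, 0.008, 0.015)
    wire_relative_amplitude: float = 60.0  # wire-drift stream RMS / dipole RMS
    exterior_relative_amplitude: float = 40.0  # stimulator feed-line leakage
    movement_rate_per_min: float = 60.0
    movement_amplitude_mm: float = 1.0    # vertical pulsation displacement
    noise_floor_fT_sqrtHz: float = 5.0
    sfreq: float = 2400.0
    duration: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if np.linalg.norm(self.dipole_position) >= self.sphere_radius:
            raise ValueError("dipole must lie strictly inside the phantom sphere")
        nyq_needed = 2 * max(self.drive_frequency, self.ringing_frequency)
        if not self.sfreq > nyq_needed:
            raise ValueError(f"sfreq must exceed {nyq_needed} Hz")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sfreq))

    @property
    def dipole_moment(self) -> np.ndarray:
        q = np.asarray(self.dipole_orientation, dtype=float)
        q = q / np.linalg.norm(q)
        return q * self.dipole_amplitude_uA * 1e-6 * self.dipole_length_m


@dataclass
class PhantomGroundTruth:
    """Everything needed to evaluate a denoiser against the simulation."""

    clean: np.ndarray            # (N, T) dipole-only sensor data, tesla
    artifacts: np.ndarray        # (N, T) sum of all artifact streams
    noise: np.ndarray            # (N, T) white sensor noise
    events: np.ndarray           # upward zero crossings of the drive, seconds
    drive: np.ndarray            # (T,) the 27 Hz drive waveform (unit amplitude)
    dipole_pattern: np.ndarray   # (N,) static dipole topography, tesla
    artifact_time_course: np.ndarray  # (T,) unit-RMS DBS waveform (zeros if off)


def dbs_artifact(
    dbs_frequency: float,
    pulse_width_us: float,
    sfreq: float,
    n_samples: int,
    ringing_frequency: float = 450.0,
    ringing_decay_s: float = 2.0e-3,
    ringing_relative_amplitude: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monopolar DBS waveform: biphasic pulse train plus inter-pulse ringing.

    Returns (time course, pulse onset sample indices).  The time course is
    dimensionless; amplitude scaling and spatial patterns are applied by the
    caller.  At 130 Hz the onsets are spaced 1/130 s = 7.7 ms apart.
    """
    if dbs_frequency < 0:
        raise ValueError("dbs_frequency must be >= 0")
    u = np.zeros(n_samples)
    if dbs_frequency == 0 or n_samples == 0:
        return u, np.array([], dtype=int)
    period = sfreq / dbs_frequency
    onsets = np.arange(0, n_samples - 2, period)
    idx = np.round(onsets).astype(int)
    # Biphasic, charge-balanced pulse: the 60 us phase is far narrower than
    # one sample, so each phase is an area-preserving single-sample impulse.
    amp = pulse_width_us * 1e-6 * sfreq
    u[idx] += amp
    u[idx + 1] -= amp
    if ringing_relative_amplitude > 0:
        t_k = np.arange(int(round(3 * ringing_decay_s * sfreq))) / sfreq
        kernel = (
            ringing_relative_amplitude
            * amp
            * np.exp(-t_k / ringing_decay_s)
            * np.sin(2 * np.pi * ringing_frequency * t_k)
        )
        deltas = np.zeros(n_samples)
        deltas[idx] = 1.0
        u = u + np.convolve(deltas, kernel)[:n_samples]
    return u, idx


def _wire_path(cfg: PhantomConfig, n_seg: int = 24):
    """Great-circle arc just inside the phantom surface (top down the +x
    side) with unit tangents: the ferromagnetic wire pair."""
    t = np.linspace(0.05, 0.95, n_seg)
    theta = t * (np.pi / 2)
    radius = 0.98 * cfg.sphere_radius
    path = radius * np.stack([np.sin(theta), np.zeros(n_seg), np.cos(theta)], axis=1)
    tangents = np.gradient(path, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return path, tangents


def _wire_pattern_at(cfg, sensors, offset) -> np.ndarray:
    path, tangents = _wire_path(cfg)
    pattern = np.zeros(sensors.n_channels)
    for p, q in zip(path, tangents):
        pattern += dipole_forward(
            p + offset, q * 1e-8, sensors, sphere_center=offset,
            sphere_radius=cfg.sphere_radius,
        )
    return pattern / path.shape[0]


_GRAD_STEP = 1e-4  # m, finite-difference step for movement gradient patterns


def _gradient_pattern(field_fn) -> np.ndarray:
    """d(pattern)/dz in tesla per metre of vertical source displacement."""
    dz = np.array([0.0, 0.0, _GRAD_STEP])
    return (field_fn(dz) - field_fn(-dz)) / (2 * _GRAD_STEP)


def movement_wire_artifact(
    cfg: PhantomConfig, sensors: SensorArray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pulsation-driven movement streams and wire topographies.

    Returns (displacement dz(t) in meters, wire static pattern, wire
    movement-gradient pattern dB/dz).  The displacement is sinusoidal at
    the pulsation rate (60 per minute -> 1 Hz); gradient patterns times
    dz(t) give the physically scaled movement artifact of each source.
    """
    if cfg.movement_rate_per_min <= 0:
        raise ValueError("movement rate must be > 0")
    t = np.arange(cfg.n_samples) / cfg.sfreq
    f_mov = cfg.movement_rate_per_min / 60.0
    dz = cfg.movement_amplitude_mm * 1e-3 * np.sin(2 * np.pi * f_mov * t)
    wire_static = _wire_pattern_at(cfg, sensors, np.zeros(3))
    wire_grad = _gradient_pattern(lambda off: _wire_pattern_at(cfg, sensors, off))
    return dz, wire_static, wire_grad


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


def simulate_phantom_recording(
    cfg: PhantomConfig, sensors: SensorArray | None = None
) -> tuple[MEGRecording, PhantomGroundTruth]:
    """Simulate one phantom run: dipole + DBS + movement/wire artifacts + noise.

    The returned ground truth satisfies the exact bookkeeping identity
    clean + artifacts + noise == recording.data.
    """
    sensors = sensors if sensors is not None else helmet_sensor_array()
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_samples
    t = np.arange(T) / cfg.sfreq

    drive = np.sin(2 * np.pi * cfg.drive_frequency * t)
    dipole_pattern = dipole_forward(
        cfg.dipole_position, cfg.dipole_moment, sensors, sphere_radius=cfg.sphere_radius
    )
    clean = dipole_pattern[:, None] * drive[None, :]
    dipole_rms = _rms(clean)

    dz, wire_static, wire_grad = movement_wire_artifact(cfg, sensors)
    artifacts = np.zeros_like(clean)

    # Movement of the dipole itself: gradient topography times displacement.
    dip_grad = _gradient_pattern(
        lambda off: dipole_forward(
            np.asarray(cfg.dipole_position) + off,
            cfg.dipole_moment,
            sensors,
            sphere_center=off,
            sphere_radius=cfg.sphere_radius,
        )
    )
    artifacts += dip_grad[:, None] * (drive * dz)[None, :]

    # --- DBS artifact: deep electrode + wire path + exterior feed line ----
    u, _ = dbs_artifact(
        cfg.dbs_frequency,
        cfg.pulse_width_us,
        cfg.sfreq,
        T,
        cfg.ringing_frequency,
        cfg.ringing_decay_s,
        cfg.ringing_relative_amplitude,
    )
    artifact_tc = np.zeros(T)
    if cfg.dbs_frequency > 0 and _rms(u) > 0:
        u_n = u / _rms(u)
        artifact_tc = u_n
        deep_moment = np.array([0.0, 1.0, 0.3]) * 1e-8
        deep_static = dipole_forward(
            cfg.electrode_position, deep_moment, sensors, sphere_radius=cfg.sphere_radius
        )
        deep_grad = _gradient_pattern(
            lambda off: dipole_forward(
                np.asarray(cfg.electrode_position) + off,
                deep_moment,
                sensors,
                sphere_center=off,
                sphere_radius=cfg.sphere_radius,
            )
        )
        ext_static = magnetic_dipole_forward(
            np.array([0.25, 0.15, 0.10]), np.array([0.0, 0.0, 1e-4]), sensors
        )
        # Deep and wire DBS conduction artifacts move with the phantom (field
        # plus gradient x displacement); the stimulator feed line is rigid.
        s_deep = 0.8 / _rms(deep_static[:, None])
        s_wire = 0.6 / _rms(wire_static[:, None])
        interior = (
            s_deep * (deep_static[:, None] * u_n[None, :]
                      + deep_grad[:, None] * (u_n * dz)[None, :])
            + s_wire * (wire_static[:, None] * u_n[None, :]
                        + wire_grad[:, None] * (u_n * dz)[None, :])
        )
        ratio = cfg.exterior_relative_amplitude / max(cfg.dbs_relative_amplitude, 1e-12)
        exterior = ext_static[:, None] / _rms(ext_static[:, None]) * u_n[None, :] * ratio
        dbs_total = interior + exterior
        dbs_total *= cfg.dbs_relative_amplitude * dipole_rms / _rms(dbs_total)
        artifacts += dbs_total

    # Wire magnetisation movement artifact (present with or without DBS):
    # the static magnetised-wire field is constant and invisible; what the
    # sensors see is the gradient topography riding on the pulsation.
    wire_move = wire_grad[:, None] * dz[None, :]
    if _rms(wire_move) > 0:
        wire_move *= cfg.wire_relative_amplitude * dipole_rms / _rms(wire_move)
        artifacts += wire_move

    sigma = cfg.noise_floor_fT_sqrtHz * 1e-15 * np.sqrt(cfg.sfreq / 2.0)
    noise = rng.normal(0.0, sigma, size=clean.shape)

    data = clean + artifacts + noise
    rec = MEGRecording(data=data, sfreq=cfg.sfreq, names=list(sensors.names))

    # Upward zero crossings of the drive: k / f_drive.
    n_ev = int(np.floor(t[-1] * cfg.drive_frequency))
    events = np.arange(n_ev + 1) / cfg.drive_frequency
    rec.events = events

    truth = PhantomGroundTruth(
        clean=clean,
        artifacts=artifacts,
        noise=noise,
        events=events,
        drive=drive,
        dipole_pattern=dipole_pattern,
        artifact_time_course=artifact_tc,
    )
    return rec, truth
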