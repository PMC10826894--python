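"""Plain-text and HDF5 interfaces: sensor CSV, recording HDF5, ROI YAML."""

from __future__ import annotations

import csv

import h5py
import numpy as np
import yaml

from .roi_filter import CuboidROI, SphericalROI
from .sss_core import MEGRecording, SensorArray

__all__ = [
    "load_sensors_csv",
    "save_sensors_csv",
    "load_recording_hdf5",
    "save_recording_hdf5",
    "load_roi_yaml",
    "save_roi_yaml",
]

_SENSOR_FIELDS = ["name", "x", "y", "z", "ox", "oy", "oz"]


def save_sensors_csv(sensors: SensorArray, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SENSOR_FIELDS)
        for name, p, o in zip(sensors.names, sensors.positions, sensors.orientations):
            writer.writerow([name, *(f"{v:.9e}" for v in (*p, *o))])


def load_sensors_csv(path) -> SensorArray:
    """Columnar text file: name, x, y, z, ox, oy, oz (meters, head frame)."""
    names, pos, ori = [], [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_SENSOR_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"sensor CSV is missing columns: {sorted(missing)}")
        for row in reader:
            names.append(row["name"])
            pos.append([float(row[k]) for k in ("x", "y", "z")])
            ori.append([float(row[k]) for k in ("ox", "oy", "oz")])
    ori = np.asarray(ori)
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    return SensorArray(positions=np.asarray(pos), orientations=ori, names=names)


def save_recording_hdf5(rec: MEGRecording, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=rec.data)
        fh.create_dataset("sfreq", data=float(rec.sfreq))
        fh.create_dataset(
            "names", data=np.array(rec.names, dtype=h5py.string_dtype("utf-8"))
        )
        if rec.events is not None:
            fh.create_dataset("events", data=np.asarray(rec.events, dtype=float))


def load_recording_hdf5(path) -> MEGRecording:
    with h5py.File(path, "r") as fh:
        data = fh["data"][()]
        sfreq = float(fh["sfreq"][()])
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in fh["names"][()]]
        events = fh["events"][()] if "events" in fh else None
    return MEGRecording(data=data, sfreq=sfreq, names=names, events=events)


def save_roi_yaml(roi, path) -> None:
    if isinstance(roi, SphericalROI):
        doc = {
            "shape": "sphere",
            "center_mm": (roi.center * 1e3).tolist(),
            "radius_mm": roi.radius * 1e3,
        }
    elif isinstance(roi, CuboidROI):
        doc = {
            "shape": "cuboid",
            "center_mm": (roi.center * 1e3).tolist(),
            "sides_mm": (roi.sides * 1e3).tolist(),
            "rotation": roi.rotation.tolist(),
        }
    else:
        raise TypeError(f"unsupported ROI type {type(roi).__name__}")
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_roi_yaml(path):
    """ROI config: {shape: sphere|cuboid, center_mm, radius_mm | sides_mm,
    rotation}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    shape = doc.get("shape")
    center = np.asarray(doc["center_mm"], dtype=float) * 1e-3
    if shape == "sphere":
        return SphericalROI(center=center, radius=float(doc["radius_mm"]) * 1e-3)
    if shape == "cuboid":
        rotation = np.asarray(doc.get("rotation", np.eye(3).tolist()), dtype=float)
        return CuboidROI(
            center=center,
            sides=np.asarray(doc["sides_mm"], dtype=float) * 1e-3,
            rotation=rotation,
        )
    raise ValueError(f"unknown ROI shape {shape!r}")
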