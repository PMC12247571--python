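"""Serialization: HDF5 for arrays/volumes, YAML for configurations.

Conventions: SI units (meters, tesla); complex datasets are stored natively
by h5py; every file carries the writing seed/config provenance as root
attributes where applicable.
"""

from __future__ import annotations

from dataclasses import asdict

import h5py
import numpy as np
import yaml

from .forward import Leadfield, SensorArray, SourceGrid
from .simulate import SensorSpectra, SimulationConfig
from .subsample import SubsamplePlan

__all__ = [
    "save_forward",
    "load_forward",
    "save_spectra",
    "load_spectra",
    "save_volume",
    "load_volume",
    "load_config",
    "save_config",
]


def save_forward(path, sensors: SensorArray, grid: SourceGrid, lead: Leadfield) -> None:
    with h5py.File(path, "w") as f:
        s = f.create_group("sensors")
        s.create_dataset("positions", data=sensors.positions)
        s.create_dataset("orientations", data=sensors.orientations)
        s.create_dataset(
            "labels", data=np.array(sensors.labels, dtype=h5py.string_dtype())
        )
        g = f.create_group("grid")
        g.create_dataset("positions", data=grid.positions)
        g.create_dataset("lattice_indices", data=grid.lattice_indices)
        g.attrs["spacing"] = grid.spacing
        l = f.create_group("leadfield")
        l.create_dataset("gain", data=lead.gain)
        l.create_dataset("valid", data=lead.valid)
        l.attrs["n_ori"] = lead.n_ori
        l.attrs["units"] = "T / (A m)"


def load_forward(path) -> tuple[SensorArray, SourceGrid, Leadfield]:
    with h5py.File(path, "r") as f:
        sensors = SensorArray(
            positions=f["sensors/positions"][()],
            orientations=f["sensors/orientations"][()],
            labels=[x.decode() for x in f["sensors/labels"][()]],
        )
        grid = SourceGrid(
            positions=f["grid/positions"][()],
            spacing=float(f["grid"].attrs["spacing"]),
            lattice_indices=f["grid/lattice_indices"][()],
        )
        lead = Leadfield(
            gain=f["leadfield/gain"][()],
            grid=grid,
            n_ori=int(f["leadfield"].attrs["n_ori"]),
            valid=f["leadfield/valid"][()],
        )
    return sensors, grid, lead


def save_spectra(path, spectra: SensorSpectra, seed: int | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coefficients", data=spectra.coefficients)
        f.attrs["role"] = spectra.role
        if seed is not None:
            f.attrs["seed"] = seed


def load_spectra(path) -> SensorSpectra:
    with h5py.File(path, "r") as f:
        return SensorSpectra(
            coefficients=f["coefficients"][()], role=str(f.attrs["role"])
        )


def save_volume(path, volume: np.ndarray, valid: np.ndarray | None = None, **attrs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=volume)
        if valid is not None:
            f.create_dataset("valid", data=valid)
        for k, v in attrs.items():
            f.attrs[k] = v


def load_volume(path) -> tuple[np.ndarray, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        valid = f["valid"][()] if "valid" in f else None
    return values, valid


def load_config(path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML (or JSON-compatible) mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimulationConfig(**data)


def save_config(path, cfg: SimulationConfig | SubsamplePlan) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)


def plan_from_mapping(data: dict) -> SubsamplePlan:
    data = dict(data)
    if "channel_range" in data:
        data["channel_range"] = tuple(data["channel_range"])
    return SubsamplePlan(**data)
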