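"""Run-container I/O: one HDF5 file per run, plus CSV/JSON derived views."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .forward import MeasurementMatrix, MeasurementSeries
from .geometry import SensorArray, VoxelGrid
from .initialization import ActivationState
from .propagation import APTemplateParams, ControlFunction, StateSpaceModel


def save_grid(group: h5py.Group, grid: VoxelGrid, types: np.ndarray | None = None) -> None:
    group.create_dataset("positions", data=grid.positions)
    group["positions"].attrs["units"] = "mm"
    group.attrs["dims"] = grid.dims
    group.attrs["voxel_size_mm"] = grid.voxel_size
    group.attrs["origin_mm"] = grid.origin
    if types is not None:
        group.create_dataset("types", data=np.asarray(types, dtype=np.int64))


def load_grid(group: h5py.Group) -> tuple[VoxelGrid, np.ndarray | None]:
    grid = VoxelGrid(
        dims=tuple(int(d) for d in group.attrs["dims"]),
        voxel_size=float(group.attrs["voxel_size_mm"]),
        origin=np.asarray(group.attrs["origin_mm"]),
        positions=group["positions"][...],
    )
    types = group["types"][...] if "types" in group else None
    return grid, types


def save_sensors(group: h5py.Group, sensors: SensorArray) -> None:
    group.create_dataset("positions", data=sensors.positions)
    group["positions"].attrs["units"] = "mm"
    group.create_dataset("orientations", data=sensors.orientations)


def load_sensors(group: h5py.Group) -> SensorArray:
    return SensorArray(
        positions=group["positions"][...], orientations=group["orientations"][...]
    )


def save_measurements(group: h5py.Group, Z: MeasurementSeries) -> None:
    ds = group.create_dataset("values", data=Z.values)
    ds.attrs["units"] = "T"
    group.attrs["sampling_rate_hz"] = Z.sampling_rate


def load_measurements(group: h5py.Group) -> MeasurementSeries:
    return MeasurementSeries(
        values=group["values"][...], sampling_rate=float(group.attrs["sampling_rate_hz"])
    )


def save_measurement_matrix(group: h5py.Group, H: MeasurementMatrix) -> None:
    ds = group.create_dataset("H", data=H.entries)
    ds.attrs["units"] = "T per normalized current unit"
    group.attrs["scale"] = H.scale


def load_measurement_matrix(group: h5py.Group) -> MeasurementMatrix:
    return MeasurementMatrix(entries=group["H"][...], scale=float(group.attrs["scale"]))


def save_model(group: h5py.Group, model: StateSpaceModel) -> None:
    conns = group.create_group("connections")
    conns.create_dataset("target", data=model.conn_target)
    conns.create_dataset("source", data=model.conn_source)
    conns.create_dataset("integer_delay", data=model.conn_delay)
    conns.create_dataset("allpass_coeff", data=model.conn_a)
    conns.create_dataset("gains", data=model.conn_gain)
    ctrl = group.create_group("control")
    ctrl.create_dataset("vector", data=model.control_vector)
    ctrl.create_dataset("waveform", data=model.control.waveform)
    ctrl["waveform"].attrs["units"] = "A/mm^2 (normalized)"
    for f, v in (
        ("onset_ms", model.control.params.onset_ms),
        ("rise_ms", model.control.params.rise_ms),
        ("plateau_ms", model.control.params.plateau_ms),
        ("repol_ms", model.control.params.repol_ms),
    ):
        ctrl.attrs[f] = v
    group.attrs["n_voxels"] = model.n_voxels
    group.attrs["fs_hz"] = model.fs
    group.attrs["convention"] = model.convention


def load_model(group: h5py.Group) -> StateSpaceModel:
    conns = group["connections"]
    ctrl = group["control"]
    params = APTemplateParams(
        onset_ms=float(ctrl.attrs["onset_ms"]),
        rise_ms=float(ctrl.attrs["rise_ms"]),
        plateau_ms=float(ctrl.attrs["plateau_ms"]),
        repol_ms=float(ctrl.attrs["repol_ms"]),
    )
    control = ControlFunction(
        waveform=ctrl["waveform"][...], fs=float(group.attrs["fs_hz"]), params=params
    )
    return StateSpaceModel(
        n_voxels=int(group.attrs["n_voxels"]),
        fs=float(group.attrs["fs_hz"]),
        conn_target=conns["target"][...],
        conn_source=conns["source"][...],
        conn_delay=conns["integer_delay"][...],
        conn_a=conns["allpass_coeff"][...],
        conn_gain=conns["gains"][...],
        control_vector=ctrl["vector"][...],
        control=control,
        convention=str(group.attrs["convention"]),
    )


def model_to_dict(model: StateSpaceModel) -> dict:
    """JSON-serializable model representation (small models / fixtures)."""
    return {
        "n_voxels": model.n_voxels,
        "fs": model.fs,
        "convention": model.convention,
        "target": model.conn_target.tolist(),
        "source": model.conn_source.tolist(),
        "integer_delay": model.conn_delay.tolist(),
        "allpass_coeff": model.conn_a.tolist(),
        "gains": model.conn_gain.tolist(),
        "control_vector": model.control_vector.tolist(),
        "control_waveform": model.control.waveform.tolist(),
        "control_params": {
            "onset_ms": model.control.params.onset_ms,
            "rise_ms": model.control.params.rise_ms,
            "plateau_ms": model.control.params.plateau_ms,
            "repol_ms": model.control.params.repol_ms,
        },
    }


def model_from_dict(data: dict) -> StateSpaceModel:
    params = APTemplateParams(**data["control_params"])
    control = ControlFunction(
        waveform=np.asarray(data["control_waveform"]), fs=data["fs"], params=params
    )
    return StateSpaceModel(
        n_voxels=int(data["n_voxels"]),
        fs=float(data["fs"]),
        conn_target=np.asarray(data["target"], dtype=np.int64),
        conn_source=np.asarray(data["source"], dtype=np.int64),
        conn_delay=np.asarray(data["integer_delay"], dtype=np.int64),
        conn_a=np.asarray(data["allpass_coeff"], dtype=float),
        conn_gain=np.asarray(data["gains"], dtype=float),
        control_vector=np.asarray(data["control_vector"], dtype=float),
        control=control,
        convention=data["convention"],
    )


def export_measurements_csv(path: str | Path, Z: MeasurementSeries) -> None:
    """Long-format CSV (time_s, channel, value_pT) for external plotting."""
    nm, ns = Z.values.shape
    t = np.repeat(np.arange(nm) / Z.sampling_rate, ns)
    ch = np.tile(np.arange(ns), nm)
    pd.DataFrame(
        {"time_s": t, "channel": ch, "value_pT": Z.values.ravel() * 1e12}
    ).to_csv(path, index=False)


def export_activation_csv(path: str | Path, activation: ActivationState) -> None:
    pd.DataFrame(
        {
            "voxel": np.arange(activation.activation_times.shape[0]),
            "sigma_ms": activation.activation_times,
            "dx": activation.directions[:, 0],
            "dy": activation.directions[:, 1],
            "dz": activation.directions[:, 2],
        }
    ).to_csv(path, index=False)


def export_loss_csv(path: str | Path, history) -> None:
    pd.DataFrame(
        {
            "epoch": np.arange(len(history)),
            "Lm": [h.Lm for h in history],
            "Lv": [h.Lv for h in history],
            "L": [h.total for h in history],
        }
    ).to_csv(path, index=False)


def save_run(
    path: str | Path,
    config_json: str,
    seed: int | None = None,
    grid: VoxelGrid | None = None,
    types: np.ndarray | None = None,
    sensors: SensorArray | None = None,
    H: MeasurementMatrix | None = None,
    Z: MeasurementSeries | None = None,
    model: StateSpaceModel | None = None,
) -> None:
    """Write (or extend) a run container."""
    with h5py.File(path, "a") as f:
        if "config" not in f.attrs:
            f.attrs["config"] = config_json
        if seed is not None:
            f.attrs["seed"] = seed
        if grid is not None and "grid" not in f:
            save_grid(f.create_group("grid"), grid, types)
        if sensors is not None and "sensors" not in f:
            save_sensors(f.create_group("sensors"), sensors)
        if H is not None and "forward" not in f:
            save_measurement_matrix(f.create_group("forward"), H)
        if Z is not None and "measurements" not in f:
            save_measurements(f.create_group("measurements"), Z)
        if model is not None:
            if "model" in f:
                del f["model"]
            save_model(f.create_group("model"), model)
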