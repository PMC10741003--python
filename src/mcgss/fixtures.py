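"""Named tiny scenarios with analytically known structure, for tests and demos."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VoxelGrid, VoxelType, build_grid, build_sensor_array
from .initialization import ActivationState, build_model
from .propagation import APTemplateParams, StateSpaceModel, simulate


@dataclass
class Fixture:
    name: str
    grid: VoxelGrid
    types: np.ndarray
    model: StateSpaceModel
    activation: ActivationState
    J: np.ndarray
    fs: float
    Nm: int


_SHORT_AP = APTemplateParams(onset_ms=5.0, rise_ms=2.0, plateau_ms=40.0, repol_ms=15.0)


def make_fixture(name: str) -> Fixture:
    """Build one of the deterministic tiny scenarios.

    ``chain3``: sinoatrial voxel plus two atrial voxels in a line (2.5 mm,
    1.1 m/s, 2 kHz), activation times 0 / 2.273 / 4.545 ms.
    ``pair2``: two voxels in a line, small enough for dense-Kalman checks.
    ``sheet5x5``: a 5x5 sheet with all tissue classes and a one-voxel
    non-conducting patch.
    """
    if name == "chain3":
        grid = build_grid((1, 3, 1), 2.5)
        types = np.array(
            [VoxelType.SINOATRIAL_NODE, VoxelType.ATRIUM, VoxelType.ATRIUM], dtype=np.int64
        )
        fs, Nm = 2000.0, 400
        model, act = build_model(grid, types, control_params=_SHORT_AP, fs=fs, Nm=Nm)
    elif name == "pair2":
        grid = build_grid((1, 2, 1), 2.5)
        types = np.array([VoxelType.SINOATRIAL_NODE, VoxelType.ATRIUM], dtype=np.int64)
        fs, Nm = 2000.0, 120
        model, act = build_model(grid, types, control_params=_SHORT_AP, fs=fs, Nm=Nm)
    elif name == "sheet5x5":
        grid = build_grid((5, 5, 1), 2.5)
        types = np.full(25, int(VoxelType.VENTRICLE), dtype=np.int64)
        types[20:25] = int(VoxelType.ATRIUM)  # top row (y=4)
        types[grid.index_of(1, 4, 0)] = int(VoxelType.SINOATRIAL_NODE)
        types[grid.index_of(2, 3, 0)] = int(VoxelType.AV_NODE)
        types[grid.index_of(2, 2, 0)] = int(VoxelType.HIS_PURKINJE)
        types[grid.index_of(2, 1, 0)] = int(VoxelType.HIS_PURKINJE)
        types[grid.index_of(0, 1, 0)] = int(VoxelType.PATHOLOGICAL)
        fs, Nm = 500.0, 300
        model, act = build_model(grid, types, control_params=_SHORT_AP, fs=fs, Nm=Nm)
    else:
        raise ValueError(f"unknown fixture {name!r}")
    J = simulate(model, Nm)
    return Fixture(
        name=name, grid=grid, types=types, model=model, activation=act, J=J, fs=fs, Nm=Nm
    )


def fixture_sensors(fixture: Fixture, n_sites: tuple[int, int, int] = (2, 2, 1)):
    """A small sensor array 50 mm above a fixture's sheet."""
    center = fixture.grid.origin + 0.5 * np.asarray(fixture.grid.extent)
    center = tuple(center + np.array([0.0, 0.0, 50.0]))
    return build_sensor_array(n_sites, (40.0, 40.0, 10.0), center, triaxial=True)
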