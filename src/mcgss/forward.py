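"""Biot-Savart forward model and the pseudoinverse baseline.

Each voxel is treated as a point source of current density; the field at a
magnetometer channel is the superposition over all voxels of

    z_i = scale * mu0/(4*pi) * o_i . ( j_k x r_hat ) / |r|^2 * V

with ``r = p_sensor - p_voxel``.  The measurement matrix ``H`` collects these
contributions per channel and per state (voxel, component), so that
``z(n) = H j(n)``.

Units: geometry enters in mm and is converted to metres here; fields are in
tesla.  The current densities carried by the state-space model are in the
normalized unit of the control drive (peak 1).  ``current_scale`` converts
that unit to A/m² inside the integrand: the strict SI reading of a density
given in A/mm² is ``current_scale=1e6``; the one-layer study maps the
normalized unit 1:1 to A/m² (``current_scale=1.0``), which is what puts the
scaled fields in the picotesla range of real magnetocardiograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SensorArray, VoxelGrid

MU0_OVER_4PI = 1e-7  # T·m/A


class SingularGeometryError(ValueError):
    """A sensor coincides (within epsilon) with a voxel center."""


@dataclass(frozen=True)
class MeasurementMatrix:
    """Dense lead-field operator, ``(Ns, 3*Nv)``, units T per normalized
    current-density unit.  Column blocks are ordered (voxel, component)."""

    entries: np.ndarray
    scale: float = 1.0

    @property
    def n_channels(self) -> int:
        return self.entries.shape[0]

    @property
    def n_states(self) -> int:
        return self.entries.shape[1]


@dataclass
class MeasurementSeries:
    """Sensor readings over time, ``(Nm, Ns)`` in tesla."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def measurement_matrix(
    grid: VoxelGrid,
    sensors: SensorArray,
    scale: float = 1.0,
    current_scale: float = 1.0,
    min_distance_mm: float = 1e-6,
) -> MeasurementMatrix:
    """Build the dense Biot-Savart lead-field matrix.

    Parameters
    ----------
    scale:
        Global dimensionless amplitude factor folded into ``H`` (the study's
        one-layer amplitude calibration factor).
    current_scale:
        Conversion from the trajectory's current-density unit to A/m²
        (1e6 for a literal A/mm² unit; 1.0 for the study's normalized unit).
    """
    p_s = sensors.positions * 1e-3  # mm -> m
    p_v = grid.positions * 1e-3
    o_s = sensors.orientations
    volume_m3 = grid.volume * 1e-9  # mm^3 -> m^3

    # r[i, k, :] = sensor_i - voxel_k
    r = p_s[:, None, :] - p_v[None, :, :]
    dist = np.linalg.norm(r, axis=2)
    if np.any(dist < min_distance_mm * 1e-3):
        raise SingularGeometryError(
            "sensor-voxel distance below epsilon; Biot-Savart integrand singular"
        )
    # (e_c x r_hat) / |r|^2 = (e_c x r) / |r|^3 for the three unit components.
    inv_d3 = 1.0 / dist**3
    ns, nv = dist.shape
    H = np.empty((ns, 3 * nv))
    basis = np.eye(3)
    prefactor = scale * current_scale * MU0_OVER_4PI * volume_m3
    for c in range(3):
        cross = np.cross(basis[c], r)  # (Ns, Nv, 3)
        # column for (voxel k, component c) is 3k + c
        H[:, c::3] = prefactor * np.einsum("ij,ikj->ik", o_s, cross) * inv_d3
    return MeasurementMatrix(entries=H, scale=float(scale))


def predict_measurements(H: MeasurementMatrix, J: np.ndarray, sampling_rate: float = 1.0) -> MeasurementSeries:
    """Apply ``z(n) = H j(n)`` to a trajectory ``J`` of shape ``(Nm, 3*Nv)``."""
    J = np.atleast_2d(np.asarray(J, dtype=float))
    if J.shape[1] != H.n_states:
        raise ValueError(f"trajectory has {J.shape[1]} states, H expects {H.n_states}")
    return MeasurementSeries(values=J @ H.entries.T, sampling_rate=sampling_rate)


def pseudoinverse_estimate(
    H: MeasurementMatrix, Z: MeasurementSeries, svd_tolerance: float = 1e-12
) -> np.ndarray:
    """Minimum-norm least-squares current densities per time step.

    Moore-Penrose inverse via SVD with relative singular-value truncation at
    ``svd_tolerance``; the textbook baseline for the ill-posed inverse
    problem.  Returns ``(Nm, 3*Nv)``.
    """
    if Z.values.shape[1] != H.n_channels:
        raise ValueError("measurement series does not match H's channel count")
    H_pinv = np.linalg.pinv(H.entries, rcond=svd_tolerance)
    return Z.values @ H_pinv.T
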