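"""Construction of the initial conduction model from geometry and tissue types.

The initial model encodes sinus rhythm on a healthy heart: conduction delays
between neighbor voxels follow from their distance and the receiving tissue's
conduction velocity, and the gain blocks are laid down by a wavefront sweep
that starts at the sinoatrial origin and activates each reachable voxel
exactly once through its earliest-processed parent.

The wavefront schedule is deliberately greedy (voxels fire in activation-time
order; the first parent to reach an unactivated compatible neighbor claims
it), which prefers fast conduction paths without solving a full shortest-path
problem.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np

from .geometry import (
    DEFAULT_CONNECTIVITY,
    DEFAULT_VELOCITIES,
    InvalidConfigurationError,
    VoxelGrid,
    VoxelType,
    neighbors,
    sinoatrial_origin,
)
from .propagation import (
    APTemplateParams,
    StateSpaceModel,
    make_control_function,
    thiran_coefficients,
)

logger = logging.getLogger(__name__)

_TIME_TOL_MS = 1e-9


@dataclass
class ActivationState:
    """Wavefront bookkeeping: activation time (ms, inf = never activated),
    unit-L1 current direction, and per-voxel connected flag."""

    activation_times: np.ndarray
    directions: np.ndarray
    connected: np.ndarray


def connection_slots(
    grid: VoxelGrid,
    types: np.ndarray,
    connectivity: frozenset[tuple[VoxelType, VoxelType]] = DEFAULT_CONNECTIVITY,
) -> tuple[np.ndarray, np.ndarray]:
    """Directed connection slots ``(targets, sources)``.

    One self-slot per voxel plus every geometric neighbor pair whose
    (source type, target type) arrow is allowed.  Ordered per target: self
    slot first, then sources ascending.
    """
    types = np.asarray(types, dtype=np.int64)
    allowed = {(int(a), int(b)) for a, b in connectivity}
    targets, sources = [], []
    for v in range(grid.n_voxels):
        targets.append(v)
        sources.append(v)
        tv = int(types[v])
        for o in neighbors(grid, v):
            if (int(types[o]), tv) in allowed:
                targets.append(v)
                sources.append(int(o))
    return np.array(targets, dtype=np.int64), np.array(sources, dtype=np.int64)


def initial_delays(
    grid: VoxelGrid,
    types: np.ndarray,
    velocities: dict[VoxelType, float],
    fs: float,
    pairs: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Group delay in samples for each (target, source) pair.

    ``tau = ||p_i - p_o|| / phi(type_i) * fs`` with the *receiving* voxel's
    conduction velocity (a wavefront slows down on entering slower tissue).
    Self-pairs get the minimum valid delay of 1 sample; delays below 1 sample
    are clamped to 1 (first-order Thiran validity) with a logged warning.
    """
    targets, sources = pairs
    types = np.asarray(types, dtype=np.int64)
    tau = np.ones(targets.shape[0], dtype=float)
    clamped = 0
    for c, (i, o) in enumerate(zip(targets, sources)):
        if i == o:
            continue
        t_i = VoxelType(int(types[i]))
        phi = velocities.get(t_i)
        if phi is None or phi <= 0:
            raise InvalidConfigurationError(f"no positive conduction velocity for {t_i.name}")
        dist_m = np.linalg.norm(grid.positions[i] - grid.positions[o]) * 1e-3
        t = dist_m / phi * fs
        if t < 1.0:
            clamped += 1
            t = 1.0
        tau[c] = t
    if clamped:
        logger.warning("clamped %d sub-sample conduction delays to 1 sample", clamped)
    return tau


def initialize_gains(
    grid: VoxelGrid,
    types: np.ndarray,
    pairs: tuple[np.ndarray, np.ndarray],
    tau_samples: np.ndarray,
    fs: float,
    origin: int | None = None,
) -> tuple[np.ndarray, ActivationState]:
    """Wavefront sweep assigning gain blocks and activation metadata.

    Starting at the sinoatrial origin (time 0 ms, direction [1, 0, 0]),
    voxels fire in order of activation time; each firing voxel claims its
    still-unconnected compatible neighbors, assigning them

    - direction ``delta_i = (p_i - p_o) / ||p_i - p_o||_1`` (unit L1 norm),
    - gain block ``c_{j,k} = delta_{i,j} * sign(delta_{o,k})``,
    - activation time ``sigma_i = sigma_o + tau_{i,o} * Ts``.

    Ties (several voxels firing at the same time, or two parents reaching
    the same child in one batch) resolve by ascending voxel index.  Returns
    the ``(Nc, 3, 3)`` gain array and the :class:`ActivationState`.
    """
    types = np.asarray(types, dtype=np.int64)
    targets, sources = pairs
    nv = grid.n_voxels
    nc = targets.shape[0]
    if origin is None:
        origin = sinoatrial_origin(types)

    # outgoing adjacency: source voxel -> list of connection indices,
    # ascending target order (slot construction already orders targets).
    outgoing: list[list[int]] = [[] for _ in range(nv)]
    for c in range(nc):
        if targets[c] != sources[c]:
            outgoing[sources[c]].append(c)

    gains = np.zeros((nc, 3, 3))
    sigma = np.full(nv, np.inf)
    delta = np.zeros((nv, 3))
    connected = np.zeros(nv, dtype=bool)

    ts_ms = 1e3 / fs
    sigma[origin] = 0.0
    delta[origin] = (1.0, 0.0, 0.0)
    connected[origin] = True
    heap: list[tuple[float, int]] = [(0.0, origin)]
    while heap:
        t_i = heap[0][0]
        batch = []
        while heap and heap[0][0] <= t_i + _TIME_TOL_MS:
            batch.append(heapq.heappop(heap)[1])
        for o in sorted(batch):
            for c in outgoing[o]:
                i = int(targets[c])
                if connected[i]:
                    continue
                step = grid.positions[i] - grid.positions[o]
                delta[i] = step / np.sum(np.abs(step))
                gains[c] = np.outer(delta[i], np.sign(delta[o]))
                sigma[i] = sigma[o] + tau_samples[c] * ts_ms
                connected[i] = True
                heapq.heappush(heap, (sigma[i], i))
    return gains, ActivationState(activation_times=sigma, directions=delta, connected=connected)


def control_vector(grid: VoxelGrid, types: np.ndarray, origin: int | None = None) -> np.ndarray:
    """Length ``3*Nv`` drive vector: 1 at the x-component of the sinoatrial
    origin, 0 elsewhere."""
    if origin is None:
        origin = sinoatrial_origin(types)
    b = np.zeros(3 * grid.n_voxels)
    b[3 * origin] = 1.0
    return b


def build_model(
    grid: VoxelGrid,
    types: np.ndarray,
    velocities: dict[VoxelType, float] | None = None,
    control_params: APTemplateParams | None = None,
    fs: float = 2000.0,
    Nm: int = 2000,
    connectivity: frozenset[tuple[VoxelType, VoxelType]] = DEFAULT_CONNECTIVITY,
    convention: str = "group_delay",
) -> tuple[StateSpaceModel, ActivationState]:
    """Compose delays, Thiran coefficients, wavefront gains, drive vector and
    control waveform into a complete initial model."""
    velocities = DEFAULT_VELOCITIES if velocities is None else velocities
    control_params = control_params or APTemplateParams()
    pairs = connection_slots(grid, types, connectivity)
    tau = initial_delays(grid, types, velocities, fs, pairs)
    ks, avs = zip(*(thiran_coefficients(t) for t in tau))
    gains, activation = initialize_gains(grid, types, pairs, tau, fs)
    b = control_vector(grid, types)
    u = make_control_function(control_params, Nm, fs)
    model = StateSpaceModel(
        n_voxels=grid.n_voxels,
        fs=float(fs),
        conn_target=pairs[0],
        conn_source=pairs[1],
        conn_delay=np.array(ks, dtype=np.int64),
        conn_a=np.array(avs, dtype=float),
        conn_gain=gains,
        control_vector=b,
        control=u,
        convention=convention,
    )
    return model, activation
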