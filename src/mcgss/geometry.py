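"""Voxelized heart-sheet geometry, tissue types, and the magnetometer array.

The myocardium is discretized into cubic voxels on a regular lattice.  Every
voxel carries one of six electrophysiological tissue types; conduction is only
possible between 26-neighborhood voxels whose type pair is an allowed arrow of
the conduction graph (sinoatrial node -> atrium -> atrioventricular node ->
His-Purkinje system -> ventricle, plus within-type propagation; pathological
tissue conducts nothing).

Geometry is stored in millimetres throughout; the forward model converts to SI
internally.  Voxel indexing is 0-based with x varying fastest, then y, then z:
``index = ix + nx * (iy + ny * iz)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np


class VoxelType(IntEnum):
    """The six electrophysiological tissue classes."""

    SINOATRIAL_NODE = 0
    ATRIUM = 1
    AV_NODE = 2
    HIS_PURKINJE = 3
    VENTRICLE = 4
    PATHOLOGICAL = 5


#: Conduction velocities in m/s for each tissue type (pathological does not
#: conduct and has no entry).  Sinoatrial node, atrium and ventricle conduct
#: at 1.1 m/s, the atrioventricular node at 0.012 m/s (the physiological AV
#: delay), the His-Purkinje system at 4.5 m/s.
DEFAULT_VELOCITIES: dict[VoxelType, float] = {
    VoxelType.SINOATRIAL_NODE: 1.1,
    VoxelType.ATRIUM: 1.1,
    VoxelType.AV_NODE: 0.012,
    VoxelType.HIS_PURKINJE: 4.5,
    VoxelType.VENTRICLE: 1.1,
}

#: Allowed directed conduction arrows (source type, target type).  Encodes the
#: conduction graph between tissue classes; pathological voxels take part in
#: no arrow.  Overridable wherever a connectivity predicate is accepted.
DEFAULT_CONNECTIVITY: frozenset[tuple[VoxelType, VoxelType]] = frozenset(
    {
        (VoxelType.SINOATRIAL_NODE, VoxelType.SINOATRIAL_NODE),
        (VoxelType.SINOATRIAL_NODE, VoxelType.ATRIUM),
        (VoxelType.ATRIUM, VoxelType.ATRIUM),
        (VoxelType.ATRIUM, VoxelType.AV_NODE),
        (VoxelType.AV_NODE, VoxelType.AV_NODE),
        (VoxelType.AV_NODE, VoxelType.HIS_PURKINJE),
        (VoxelType.HIS_PURKINJE, VoxelType.HIS_PURKINJE),
        (VoxelType.HIS_PURKINJE, VoxelType.VENTRICLE),
        (VoxelType.VENTRICLE, VoxelType.VENTRICLE),
    }
)


class InvalidConfigurationError(ValueError):
    """Raised for geometrically or physically impossible configurations."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular lattice of cubic voxels.

    Attributes
    ----------
    dims:
        Lattice extents ``(nx, ny, nz)``.
    voxel_size:
        Edge length of the cubic voxels in mm.
    origin:
        Position of the lattice corner in mm; the first voxel center sits at
        ``origin + voxel_size / 2``.
    positions:
        ``(Nv, 3)`` voxel centers in mm.
    """

    dims: tuple[int, int, int]
    voxel_size: float
    origin: np.ndarray
    positions: np.ndarray = field(repr=False)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def volume(self) -> float:
        """Voxel volume in mm³."""
        return float(self.voxel_size**3)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the sheet in mm, ``dims * voxel_size``."""
        return tuple(d * self.voxel_size for d in self.dims)

    def index_of(self, ix: int, iy: int, iz: int) -> int:
        nx, ny, nz = self.dims
        if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
            raise IndexError(f"lattice coordinate ({ix}, {iy}, {iz}) out of range")
        return ix + nx * (iy + ny * iz)

    def lattice_coords(self, v: int) -> tuple[int, int, int]:
        nx, ny, nz = self.dims
        if not 0 <= v < self.n_voxels:
            raise IndexError(f"voxel index {v} out of range [0, {self.n_voxels})")
        ix = v % nx
        iy = (v // nx) % ny
        iz = v // (nx * ny)
        return ix, iy, iz


def build_grid(
    dims: tuple[int, int, int],
    voxel_size: float,
    origin: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> VoxelGrid:
    """Construct a regular voxel lattice.

    Voxel centers sit at ``origin + (i + 1/2) * voxel_size`` per axis; the
    index order is x fastest, then y, then z.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 1 for d in dims):
        raise InvalidConfigurationError(f"grid dims must be three positive integers, got {dims}")
    if voxel_size <= 0:
        raise InvalidConfigurationError(f"voxel_size must be positive, got {voxel_size}")
    origin = np.asarray(origin, dtype=float)
    nx, ny, nz = dims
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    lattice = np.stack(
        [ix.ravel(order="F"), iy.ravel(order="F"), iz.ravel(order="F")], axis=1
    )
    positions = origin + (lattice + 0.5) * voxel_size
    return VoxelGrid(dims=dims, voxel_size=float(voxel_size), origin=origin, positions=positions)


def neighbors(grid: VoxelGrid, v: int) -> np.ndarray:
    """Indices of the up to 26 lattice neighbors of voxel ``v``, ascending."""
    ix, iy, iz = grid.lattice_coords(v)
    nx, ny, nz = grid.dims
    out = []
    for dz in (-1, 0, 1):
        jz = iz + dz
        if not 0 <= jz < nz:
            continue
        for dy in (-1, 0, 1):
            jy = iy + dy
            if not 0 <= jy < ny:
                continue
            for dx in (-1, 0, 1):
                if dx == 0 and dy == 0 and dz == 0:
                    continue
                jx = ix + dx
                if not 0 <= jx < nx:
                    continue
                out.append(jx + nx * (jy + ny * jz))
    return np.array(sorted(out), dtype=np.int64)


def neighbor_pairs(grid: VoxelGrid) -> np.ndarray:
    """All directed neighbor pairs ``(target, source)`` as an ``(Np, 2)`` array.

    Ordered by target index, then source index (deterministic).
    """
    pairs = []
    for v in range(grid.n_voxels):
        for o in neighbors(grid, v):
            pairs.append((v, int(o)))
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)


@dataclass(frozen=True)
class SensorArray:
    """Single-axis magnetometer channels: positions (mm) and unit orientations."""

    positions: np.ndarray
    orientations: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def __post_init__(self):
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidConfigurationError("sensor orientations must be unit vectors")


def build_sensor_array(
    grid_counts: tuple[int, int, int],
    extent: tuple[float, float, float],
    center: tuple[float, float, float],
    triaxial: bool = True,
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> SensorArray:
    """Regular lattice of magnetometer sites spanning ``extent`` around ``center``.

    With ``triaxial=True`` every site contributes three channels oriented along
    x, y and z; otherwise one channel per site with the given orientation.
    Sites along an axis with count ``c > 1`` are spaced ``extent / (c - 1)``
    apart (the lattice spans the full extent); a count of 1 places the site at
    the center of that axis.
    """
    grid_counts = tuple(int(c) for c in grid_counts)
    if any(c < 1 for c in grid_counts):
        raise InvalidConfigurationError(f"sensor grid counts must be >= 1, got {grid_counts}")
    center = np.asarray(center, dtype=float)
    extent = np.asarray(extent, dtype=float)
    axes = []
    for c, e in zip(grid_counts, extent):
        if c == 1:
            axes.append(np.zeros(1))
        else:
            axes.append(np.linspace(-e / 2.0, e / 2.0, c))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    sites = center + np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    if triaxial:
        positions = np.repeat(sites, 3, axis=0)
        orientations = np.tile(np.eye(3), (sites.shape[0], 1))
    else:
        positions = sites
        o = np.asarray(orientation, dtype=float)
        o = o / np.linalg.norm(o)
        orientations = np.tile(o, (sites.shape[0], 1))
    return SensorArray(positions=positions, orientations=orientations)


@dataclass(frozen=True)
class SheetLayout:
    """Parameterized region layout for the one-layer heart sheet.

    All coordinates are lattice indices on the (nx, ny) sheet (nz = 1).  The
    sheet is an unrolled heart surface: atria occupy the top rows, ventricles
    the bottom, the single-voxel atrioventricular node sits between them on
    the septum, and the His-Purkinje system runs down the septum to a wide
    apical bundle-branch row, so the ventricular wavefront sweeps coherently
    from apex to base.  The optional pathological patch is a rectangle inside
    the ventricular region.

    The default constants approximate the region shapes of the reference
    one-layer setup; they were fixed once so that the simulated field
    amplitudes match the setup's stated calibration (~100 pT R-peak at the
    fixed amplitude factor, GT-vs-initial peak difference ~22.5 pT).
    """

    atria_min_row: int = 25
    sa_site: tuple[int, int] = (4, 33)
    av_site: tuple[int, int] = (13, 24)
    his_column_x: int = 13
    his_rows: tuple[int, int] = (2, 23)
    his_branch_row: int = 2
    his_branch_cols: tuple[int, int] = (3, 22)
    patch_enabled: bool = False
    patch_cols: tuple[int, int] = (4, 9)
    patch_rows: tuple[int, int] = (11, 17)


def default_layout(patch_enabled: bool = False, **overrides) -> SheetLayout:
    """The standard one-layer layout; ``patch_enabled=True`` gives the
    ground-truth variant with the non-conducting patch in the right ventricle,
    ``False`` the healthy initial-model variant."""
    return replace(SheetLayout(patch_enabled=patch_enabled), **overrides)


def assign_default_types(grid: VoxelGrid, layout: SheetLayout) -> np.ndarray:
    """Assign one tissue type per voxel on a one-layer sheet.

    Returns a length-``Nv`` int array of :class:`VoxelType`.  The ground-truth
    and initial layouts differ only inside the pathological patch.
    """
    nx, ny, nz = grid.dims
    if nz != 1:
        raise InvalidConfigurationError("default type assignment requires a one-layer grid (nz=1)")
    types = np.full(grid.n_voxels, int(VoxelType.VENTRICLE), dtype=np.int64)

    def idx(ix, iy):
        return grid.index_of(ix, iy, 0)

    # Atria: all rows from atria_min_row upward.
    for iy in range(min(layout.atria_min_row, ny), ny):
        for ix in range(nx):
            types[idx(ix, iy)] = int(VoxelType.ATRIUM)
    # His-Purkinje septal column and apical bundle branches.
    r0, r1 = layout.his_rows
    for iy in range(max(r0, 0), min(r1, ny - 1) + 1):
        if 0 <= layout.his_column_x < nx:
            types[idx(layout.his_column_x, iy)] = int(VoxelType.HIS_PURKINJE)
    c0, c1 = layout.his_branch_cols
    if 0 <= layout.his_branch_row < ny:
        for ix in range(max(c0, 0), min(c1, nx - 1) + 1):
            types[idx(ix, layout.his_branch_row)] = int(VoxelType.HIS_PURKINJE)
    # Single-voxel atrioventricular node on the septum.
    ax, ay = layout.av_site
    if not (0 <= ax < nx and 0 <= ay < ny):
        raise InvalidConfigurationError(f"AV-node site {layout.av_site} outside the grid")
    types[idx(ax, ay)] = int(VoxelType.AV_NODE)
    # Single-voxel sinoatrial node inside the atria.
    sx, sy = layout.sa_site
    if not (0 <= sx < nx and 0 <= sy < ny):
        raise InvalidConfigurationError(f"sinoatrial site {layout.sa_site} outside the grid")
    types[idx(sx, sy)] = int(VoxelType.SINOATRIAL_NODE)
    # Optional non-conducting patch, clipped to the ventricular region.
    if layout.patch_enabled:
        p0, p1 = layout.patch_cols
        q0, q1 = layout.patch_rows
        clipped = False
        for iy in range(q0, q1 + 1):
            for ix in range(p0, p1 + 1):
                if not (0 <= ix < nx and 0 <= iy < ny):
                    clipped = True
                    continue
                i = idx(ix, iy)
                if types[i] != int(VoxelType.VENTRICLE):
                    clipped = True
                    continue
                types[i] = int(VoxelType.PATHOLOGICAL)
        if clipped:
            warnings.warn(
                "pathological patch extends outside the ventricular region; clipped",
                stacklevel=2,
            )
    if not np.any(types == int(VoxelType.SINOATRIAL_NODE)):
        raise InvalidConfigurationError("layout produced no sinoatrial voxel")
    return types


def sinoatrial_origin(types: np.ndarray) -> int:
    """The designated sinoatrial origin voxel: the lowest-index SA voxel."""
    sa = np.flatnonzero(np.asarray(types) == int(VoxelType.SINOATRIAL_NODE))
    if sa.size == 0:
        raise InvalidConfigurationError("no sinoatrial voxel present")
    return int(sa[0])
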