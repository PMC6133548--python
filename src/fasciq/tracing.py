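"""Brightest-path tracing of single neurites in 3D fluorescence stacks.

A labeled dendrite appears as a bright, roughly tubular ridge in its own
channel.  Given user-supplied start and end voxels (tip and cell-body side),
the trace is the minimum-cost path on the voxel graph where cost is inverse
intensity weighted by physical step length — Dijkstra's shortest path follows
the brightest corridor, i.e. the dendrite itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

__all__ = ["VoxelStack", "DendriteTrace", "brightest_path", "trim_trace", "path_cost"]

#: intensity offset (in units of the normalized 8-bit-like scale) added before
#: inversion so zero-intensity voxels are merely expensive, never infinite.
EPSILON = 1.0

#: internal normalization ceiling: stacks are rescaled so max intensity = 255
#: before inversion, making traces exactly invariant to global intensity scaling.
_NORM_MAX = 255.0


@dataclass
class VoxelStack:
    """One channel of a 3D image stack with anisotropic voxel spacing.

    ``intensities`` is indexed ``[z, y, x]`` (TIFF page order);
    ``spacing_um`` is ``(x, y, z)`` physical voxel size in micrometers.
    """

    intensities: np.ndarray
    spacing_um: tuple[float, float, float]
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError(
                f"expected a non-empty 3D stack, got shape {self.intensities.shape}"
            )
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing_um must be three positive values, got {self.spacing_um}")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def voxel_to_um(self, voxels_xyz: np.ndarray) -> np.ndarray:
        """Convert (n, 3) voxel indices in (x, y, z) order to physical µm."""
        return np.asarray(voxels_xyz, dtype=float) * np.asarray(self.spacing_um)


@dataclass
class DendriteTrace:
    """Ordered 3D polyline for one dendrite, coordinates in µm (x, y, z)."""

    points: np.ndarray
    label: str = ""
    source: str = "traced"  # traced | ground_truth | imported

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) == 0:
            raise ValueError("trace points must be a non-empty (n, 3) array")
        if len(self.points) > 1:
            steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if np.any(steps == 0):
                raise ValueError("consecutive trace points must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def arc_length_um(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


# 26-connectivity: the 13 offsets spanning half the neighborhood (the graph is
# undirected, so each unordered voxel pair appears once).
_HALF_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]


def _inverse_intensity(stack: VoxelStack) -> np.ndarray:
    """Per-voxel traversal cost: inverse of max-normalized intensity."""
    inten = stack.intensities.astype(float)
    peak = inten.max()
    if peak > 0:
        inten = inten * (_NORM_MAX / peak)
    return 1.0 / (inten + EPSILON)


def _build_voxel_graph(stack: VoxelStack) -> coo_matrix:
    nz, ny, nx = stack.shape_zyx
    sx, sy, sz = stack.spacing_um
    inv = _inverse_intensity(stack).ravel()
    idx = np.arange(nz * ny * nx).reshape(nz, ny, nx)

    rows, cols, weights = [], [], []
    for dz, dy, dx in _HALF_OFFSETS:
        src = idx[
            max(0, -dz) : nz - max(0, dz),
            max(0, -dy) : ny - max(0, dy),
            max(0, -dx) : nx - max(0, dx),
        ].ravel()
        if src.size == 0:
            continue
        dst = idx[
            max(0, dz) : nz + min(0, dz) or nz,
            max(0, dy) : ny + min(0, dy) or ny,
            max(0, dx) : nx + min(0, dx) or nx,
        ].ravel()
        step = float(np.sqrt((dx * sx) ** 2 + (dy * sy) ** 2 + (dz * sz) ** 2))
        rows.append(src)
        cols.append(dst)
        weights.append((inv[src] + inv[dst]) * (0.5 * step))
    n = nz * ny * nx
    return coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def _check_in_bounds(voxel_xyz: Sequence[int], shape_zyx: tuple[int, int, int], name: str) -> tuple[int, int, int]:
    x, y, z = (int(v) for v in voxel_xyz)
    nz, ny, nx = shape_zyx
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise ValueError(
            f"{name} voxel (x={x}, y={y}, z={z}) outside stack of shape "
            f"(nx={nx}, ny={ny}, nz={nz})"
        )
    return x, y, z


def brightest_path(
    stack: VoxelStack,
    start: Sequence[int],
    end: Sequence[int],
) -> DendriteTrace:
    """Trace the brightest path between two voxels.

    Parameters
    ----------
    stack
        Single-channel stack.
    start, end
        Voxel indices in ``(x, y, z)`` order.

    Returns
    -------
    DendriteTrace
        Path coordinates in physical µm (``index × spacing``), ordered from
        ``start`` to ``end``.

    Notes
    -----
    The voxel graph is 26-connected; an edge between voxels u, v costs the
    mean of their inverse normalized intensities times the physical Euclidean
    step length, so anisotropic z-spacing is handled correctly and the result
    is invariant to multiplying all intensities by a positive constant.
    """
    x0, y0, z0 = _check_in_bounds(start, stack.shape_zyx, "start")
    x1, y1, z1 = _check_in_bounds(end, stack.shape_zyx, "end")
    spacing = np.asarray(stack.spacing_um)
    if (x0, y0, z0) == (x1, y1, z1):
        return DendriteTrace(
            points=np.array([[x0, y0, z0]], dtype=float) * spacing,
            label=stack.channel_label,
            source="traced",
        )

    nz, ny, nx = stack.shape_zyx
    graph = _build_voxel_graph(stack)
    start_flat = (z0 * ny + y0) * nx + x0
    end_flat = (z1 * ny + y1) * nx + x1
    _, predecessors = _csgraph_dijkstra(
        graph, directed=False, indices=start_flat, return_predecessors=True
    )
    flat_path = [end_flat]
    while flat_path[-1] != start_flat:
        prev = predecessors[flat_path[-1]]
        if prev < 0:  # unreachable cannot happen on a connected grid; guard anyway
            raise RuntimeError("end voxel not reachable from start voxel")
        flat_path.append(int(prev))
    flat_path.reverse()

    flat = np.asarray(flat_path)
    zs, rem = np.divmod(flat, ny * nx)
    ys, xs = np.divmod(rem, nx)
    points_um = np.column_stack([xs, ys, zs]).astype(float) * spacing
    return DendriteTrace(points=points_um, label=stack.channel_label, source="traced")


def path_cost(stack: VoxelStack, voxels_xyz: np.ndarray) -> float:
    """Cost of an explicit voxel path under the brightest-path edge weight.

    ``voxels_xyz`` is an (n, 3) array of in-bounds voxel indices with each
    consecutive pair 26-adjacent.  Used to compare alternative paths against
    the Dijkstra optimum.
    """
    voxels = np.asarray(voxels_xyz, dtype=int)
    if voxels.ndim != 2 or voxels.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of voxel indices")
    steps = np.diff(voxels, axis=0)
    if np.any(np.abs(steps) > 1) or np.any(np.all(steps == 0, axis=1)):
        raise ValueError("consecutive voxels must be distinct and 26-adjacent")
    inv = _inverse_intensity(stack)
    vals = inv[voxels[:, 2], voxels[:, 1], voxels[:, 0]]
    lengths = np.linalg.norm(steps * np.asarray(stack.spacing_um), axis=1)
    return float((0.5 * (vals[:-1] + vals[1:]) * lengths).sum())


def trim_trace(trace: DendriteTrace, n_head: int, n_tail: int) -> DendriteTrace:
    """Drop ``n_head`` points from the start and ``n_tail`` from the end.

    Mirrors the manual-correction workflow in which mistraced rows at the
    distal/proximal ends are deleted from the distance spreadsheet.
    """
    if n_head < 0 or n_tail < 0:
        raise ValueError("trim counts must be non-negative")
    n = len(trace.points)
    if n_head + n_tail >= n:
        raise ValueError(
            f"cannot trim {n_head} + {n_tail} points from a {n}-point trace"
        )
    stop = n - n_tail
    return DendriteTrace(
        points=trace.points[n_head:stop].copy(),
        label=trace.label,
        source=trace.source,
    )
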