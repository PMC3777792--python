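"""Voxel-wise direct/indirect connectivity graphs and the VISC metric.

A voxel is identified by its center; voxel boundaries are half-open,
``[c - s/2, c + s/2)`` around each center, so a point lying exactly on a
shared face belongs to the higher-index voxel.

From a set of streamlines, the binary direct-connectivity matrix ``X`` over
voxel linear indices has ``x_ij = 1`` when voxels i and j are both penetrated
by at least one common fiber: each fiber contributes the full clique over the
voxels it penetrates, and ``X`` is the union of those per-fiber cliques.  The
indirect matrix ``Y`` has ``y_ij = 1`` when i and j share a directly connected
voxel but are not directly connected themselves (two hops, not one).

The voxel-wise indirect structural connectivity of voxel i is the total
number of direct connections of its indirect neighbors divided by the number
of indirect neighbors raised to the contrast exponent alpha::

    VISC_alpha(i) = (y(i) X 1) / (y(i) 1)**alpha,   alpha in [0, 1]

With alpha = 1 this is the mean direct-connection count over indirect
neighbors; with alpha = 0 the denominator is 1 and VISC equals the raw total.
Voxels with no indirect neighbors get VISC = 0.

All matrices are stored sparse; a dense n_voxels x n_voxels array is never
materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .dti import ScalarMap

__all__ = [
    "VoxelGrid",
    "ConnectivityGraph",
    "ViscParams",
    "voxels_penetrated",
    "build_direct",
    "build_indirect",
    "compute_visc",
    "visc_values",
    "fiber_count_map",
    "mean_fiber_length_map",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular voxel lattice in mm coordinates.

    The volume spans ``[0, shape_d * voxel_size_d)`` along each axis; the
    center of voxel ``(i, j, k)`` is at ``((i + .5) sx, (j + .5) sy,
    (k + .5) sz)``.  Linear indices follow C order (``np.ravel_multi_index``).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape):
            raise ValueError("grid dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the volume in mm per axis."""
        return np.asarray(self.shape) * np.asarray(self.voxel_size)

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        s = self.voxel_size[axis]
        return (np.arange(self.shape[axis]) + 0.5) * s

    def center_of(self, ijk) -> np.ndarray:
        """Center (mm) of voxel(s) given integer index triplets (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return (ijk + 0.5) * np.asarray(self.voxel_size)

    def point_to_ijk(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map mm points (N, 3) to integer voxel triplets; also return
        an in-bounds mask.  Half-open boundary rule (floor)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ijk = np.floor(pts / np.asarray(self.voxel_size)).astype(np.int64)
        inside = np.all((ijk >= 0) & (ijk < np.asarray(self.shape)), axis=1)
        return ijk, inside

    def ravel(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk)
        return np.ravel_multi_index((ijk[..., 0], ijk[..., 1], ijk[..., 2]), self.shape)

    def unravel(self, lin: np.ndarray) -> np.ndarray:
        i, j, k = np.unravel_index(np.asarray(lin), self.shape)
        return np.stack([i, j, k], axis=-1)


@dataclass(frozen=True)
class ViscParams:
    """Contrast exponent for the indirect-connectivity metric."""

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass
class ConnectivityGraph:
    """Sparse voxel connectivity: direct matrix X and derived indirect Y."""

    direct: sp.csr_matrix
    grid: VoxelGrid
    indirect: sp.csr_matrix | None = field(default=None)

    def ensure_indirect(self) -> sp.csr_matrix:
        if self.indirect is None:
            self.indirect = build_indirect(self.direct)
        return self.indirect


def voxels_penetrated(points: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Ordered unique linear indices of voxels containing >= 1 point.

    Out-of-grid points are skipped.  Order is first-visit order along the
    streamline; duplicates are collapsed.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return np.empty(0, dtype=np.int64)
    ijk, inside = grid.point_to_ijk(pts)
    lin = grid.ravel(ijk[inside])
    if lin.size == 0:
        return lin
    _, first = np.unique(lin, return_index=True)
    return lin[np.sort(first)]


def _clique_pairs(vox: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All ordered pairs (i != j) among a fiber's penetrated voxels."""
    k = vox.shape[0]
    rows = np.repeat(vox, k)
    cols = np.tile(vox, k)
    keep = rows != cols
    return rows[keep], cols[keep]


def _chain_pairs(vox: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Only consecutive penetrated voxels along the fiber (sensitivity mode)."""
    a, b = vox[:-1], vox[1:]
    keep = a != b
    rows = np.concatenate([a[keep], b[keep]])
    cols = np.concatenate([b[keep], a[keep]])
    return rows, cols


def build_direct(fibers, grid: VoxelGrid, mode: str = "clique") -> ConnectivityGraph:
    """Direct connectivity matrix X from a fiber set.

    ``mode='clique'`` (default) connects every pair of voxels a fiber
    penetrates, the literal per-fiber definition; ``mode='chain'`` connects
    only consecutive voxels along each fiber, exposed for sensitivity
    analysis.  The result is symmetric, binary, zero-diagonal.
    """
    if mode not in ("clique", "chain"):
        raise ValueError(f"unknown connectivity mode: {mode!r}")
    pair_fn = _clique_pairs if mode == "clique" else _chain_pairs
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for f in fibers:
        pts = f.points if hasattr(f, "points") else np.asarray(f)
        vox = voxels_penetrated(pts, grid)
        if vox.shape[0] < 2:
            continue
        r, c = pair_fn(vox)
        rows.append(r)
        cols.append(c)
    n = grid.n_voxels
    if not rows:
        x = sp.csr_matrix((n, n), dtype=np.int8)
        return ConnectivityGraph(direct=x, grid=grid)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    x = sp.coo_matrix((np.ones(r.shape[0], dtype=np.int8), (r, c)), shape=(n, n))
    x = x.tocsr()
    x.data[:] = 1  # union of per-fiber cliques, binary
    x.setdiag(0)
    x.eliminate_zeros()
    return ConnectivityGraph(direct=x, grid=grid)


def build_indirect(x: sp.spmatrix) -> sp.csr_matrix:
    """Indirect matrix Y: two-hop-reachable but not directly connected.

    ``y_ij = 1`` iff i != j, ``(X @ X)_ij > 0`` and ``x_ij = 0``.
    """
    x = x.tocsr().astype(bool)
    two_hop = (x @ x).tocsr()
    y = two_hop.astype(np.int8)
    y.setdiag(0)
    # remove entries that are also direct connections
    y = y - y.multiply(x)
    y.eliminate_zeros()
    y.data[:] = 1
    return y.tocsr()


def visc_values(
    x: sp.spmatrix, y: sp.spmatrix, params: ViscParams = ViscParams()
) -> np.ndarray:
    """Per-voxel VISC over linear indices (dense 1D vector).

    Numerator: y(i) X 1, total direct connections of i's indirect neighbors.
    Denominator: (y(i) 1)**alpha.  Zero where a voxel has no indirect
    neighbors.
    """
    degree = np.asarray(x.sum(axis=1)).ravel().astype(float)  # X 1
    num = np.asarray(y @ degree).ravel()  # y(i) X 1
    n_indirect = np.asarray(y.sum(axis=1)).ravel().astype(float)  # y(i) 1
    out = np.zeros_like(num, dtype=float)
    nz = n_indirect > 0
    out[nz] = num[nz] / n_indirect[nz] ** params.alpha
    return out


def compute_visc(
    graph: ConnectivityGraph, params: ViscParams = ViscParams()
) -> ScalarMap:
    """VISC scalar map on the graph's voxel grid."""
    y = graph.ensure_indirect()
    vals = visc_values(graph.direct, y, params)
    return ScalarMap(
        vals.reshape(graph.grid.shape),
        "VISC",
        voxel_size=graph.grid.voxel_size,
    )


def _per_voxel_fiber_stats(fibers, grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    counts = np.zeros(grid.n_voxels, dtype=float)
    length_sum = np.zeros(grid.n_voxels, dtype=float)
    for f in fibers:
        pts = f.points if hasattr(f, "points") else np.asarray(f)
        vox = voxels_penetrated(pts, grid)
        if vox.size == 0:
            continue
        if hasattr(f, "length"):
            flen = float(f.length)
        else:
            p = np.asarray(pts, dtype=float)
            flen = float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())
        counts[vox] += 1
        length_sum[vox] += flen
    return counts, length_sum


def fiber_count_map(fibers, grid: VoxelGrid) -> ScalarMap:
    """Number of fibers penetrating each voxel."""
    counts, _ = _per_voxel_fiber_stats(fibers, grid)
    return ScalarMap(
        counts.reshape(grid.shape), "fiber_count", voxel_size=grid.voxel_size
    )


def mean_fiber_length_map(fibers, grid: VoxelGrid) -> ScalarMap:
    """Mean physical length (mm) of the fibers penetrating each voxel;
    0 where no fiber penetrates."""
    counts, length_sum = _per_voxel_fiber_stats(fibers, grid)
    mean = np.zeros_like(counts)
    nz = counts > 0
    mean[nz] = length_sum[nz] / counts[nz]
    return ScalarMap(
        mean.reshape(grid.shape), "mean_fiber_length", voxel_size=grid.voxel_size
    )
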