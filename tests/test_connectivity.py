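"""Connectivity graphs and the VISC metric, including a brute-force
graph-theoretic oracle."""

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from visconn import (
    ConnectivityGraph,
    ViscParams,
    VoxelGrid,
    build_direct,
    build_indirect,
    compute_visc,
    fiber_count_map,
    mean_fiber_length_map,
    visc_values,
    voxels_penetrated,
)


# ---------------------------------------------------------------------------
# worked example


def test_worked_example_exact(worked_example):
    g = build_direct(worked_example.fibers, worked_example.grid)
    y = g.ensure_indirect()
    a = worked_example.linear_index("A")

    assert g.direct[a].nnz == 2  # direct neighbors of A: B, C
    assert y[a].nnz == 3  # indirect neighbors of A: D, E, F

    direct_of = {
        k: set(g.direct[worked_example.linear_index(k)].indices) for k in "ABCDEF"
    }
    idx = {worked_example.linear_index(k): k for k in "ABCDEF"}
    assert {idx[i] for i in direct_of["A"]} == {"B", "C"}
    # per-voxel direct-connection counts
    degrees = {k: len(v) for k, v in direct_of.items()}
    assert degrees == {"A": 2, "B": 4, "C": 3, "D": 2, "E": 2, "F": 1}

    v1 = compute_visc(g, ViscParams(alpha=1.0)).values.ravel()
    v0 = compute_visc(g, ViscParams(alpha=0.0)).values.ravel()
    assert v1[a] == pytest.approx(5.0 / 3.0)
    assert v0[a] == pytest.approx(5.0)


def test_worked_example_matrix_properties(worked_example):
    g = build_direct(worked_example.fibers, worked_example.grid)
    x = g.direct
    assert (x != x.T).nnz == 0  # symmetric
    assert x.diagonal().sum() == 0  # zero diagonal
    assert set(np.unique(x.data)) == {1}  # binary
    y = g.ensure_indirect()
    assert (y != y.T).nnz == 0
    assert y.multiply(x).nnz == 0  # indirect excludes direct
    assert y.diagonal().sum() == 0


def test_fiber_maps(worked_example):
    counts = fiber_count_map(worked_example.fibers, worked_example.grid).values.ravel()
    lengths = mean_fiber_length_map(worked_example.fibers, worked_example.grid).values.ravel()
    li = worked_example.linear_index
    assert counts[li("B")] == 2  # fibers 1 and 2
    assert counts[li("C")] == 2  # fibers 1 and 3
    assert counts[li("F")] == 1
    # fiber lengths: {A,B,C} = 2 mm, {D,B,E} = 1 + sqrt(2) mm, {C,F} = 1 mm
    assert lengths[li("B")] == pytest.approx((2.0 + 1.0 + np.sqrt(2.0)) / 2)
    assert lengths[li("C")] == pytest.approx(1.5)
    assert lengths[li("A")] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# brute-force oracle


def _brute_force_visc(adj: np.ndarray, alpha: float) -> np.ndarray:
    """Independent VISC computation via networkx shortest-path lengths."""
    g = nx.from_numpy_array(adj)
    deg = adj.sum(axis=1)
    out = np.zeros(adj.shape[0])
    for i in range(adj.shape[0]):
        dist = nx.single_source_shortest_path_length(g, i, cutoff=2)
        indirect = [j for j, d in dist.items() if d == 2]
        if indirect:
            out[i] = deg[indirect].sum() / len(indirect) ** alpha
    return out


def test_visc_matches_brute_force_on_random_graphs():
    for seed in range(100):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        p = rng.uniform(0.03, 0.25)
        upper = np.triu(rng.random((n, n)) < p, k=1)
        adj = (upper | upper.T).astype(np.int8)
        x = sp.csr_matrix(adj)
        y = build_indirect(x)
        for alpha in (0.0, 0.5, 1.0):
            got = visc_values(x, y, ViscParams(alpha=alpha))
            want = _brute_force_visc(adj, alpha)
            np.testing.assert_allclose(got, want, atol=1e-12,
                                       err_msg=f"seed={seed} alpha={alpha}")


# ---------------------------------------------------------------------------
# voxel grid geometry


def test_grid_half_open_boundaries():
    grid = VoxelGrid((4, 4, 4), (1.0, 1.0, 1.0))
    ijk, inside = grid.point_to_ijk(np.array([[1.0, 0.5, 0.5]]))
    assert inside[0]
    assert tuple(ijk[0]) == (1, 0, 0)  # face point joins the higher voxel
    _, inside = grid.point_to_ijk(np.array([[4.0, 0.5, 0.5], [-0.01, 1, 1]]))
    assert not inside.any()


def test_grid_centers_and_ravel():
    grid = VoxelGrid((3, 2, 1), (2.0, 1.0, 1.0))
    np.testing.assert_allclose(grid.center_of([1, 0, 0]), [3.0, 0.5, 0.5])
    lin = grid.ravel(np.array([2, 1, 0]))
    np.testing.assert_array_equal(grid.unravel(lin), [2, 1, 0])
    assert grid.n_voxels == 6
    np.testing.assert_allclose(grid.extent, [6.0, 2.0, 1.0])


def test_grid_validation():
    with pytest.raises(ValueError):
        VoxelGrid((0, 2, 2))
    with pytest.raises(ValueError):
        VoxelGrid((2, 2, 2), (1.0, -1.0, 1.0))


def test_voxels_penetrated_order_and_skip():
    grid = VoxelGrid((3, 1, 1))
    pts = np.array(
        [[2.5, 0.5, 0.5], [2.6, 0.5, 0.5], [0.5, 0.5, 0.5], [9.0, 0.5, 0.5]]
    )
    vox = voxels_penetrated(pts, grid)
    # first-visit order, duplicate collapsed, out-of-grid point skipped
    np.testing.assert_array_equal(vox, [2, 0])
    assert voxels_penetrated(np.empty((0, 3)), grid).size == 0


# ---------------------------------------------------------------------------
# modes and parameters


def test_chain_mode_relaxes_clique():
    grid = VoxelGrid((3, 1, 1))
    fiber = [np.array([[0.5, 0.5, 0.5], [1.5, 0.5, 0.5], [2.5, 0.5, 0.5]])]
    clique = build_direct(fiber, grid, mode="clique").direct
    chain = build_direct(fiber, grid, mode="chain").direct
    assert clique[0, 2] == 1  # endpoints directly connected in clique mode
    assert chain[0, 2] == 0  # ... but only via the middle voxel in chain mode
    y = build_indirect(chain)
    assert y[0, 2] == 1


def test_unknown_mode_raises(worked_example):
    with pytest.raises(ValueError, match="mode"):
        build_direct(worked_example.fibers, worked_example.grid, mode="loop")


def test_alpha_validation():
    with pytest.raises(ValueError, match="alpha"):
        ViscParams(alpha=1.5)
    with pytest.raises(ValueError, match="alpha"):
        ViscParams(alpha=-0.1)


def test_no_fibers_gives_zero_visc():
    grid = VoxelGrid((2, 2, 2))
    g = build_direct([], grid)
    assert g.direct.nnz == 0
    assert compute_visc(g).values.sum() == 0.0


def test_isolated_voxel_visc_zero(worked_example):
    """A voxel with no indirect neighbors gets VISC = 0, not NaN/inf."""
    grid = VoxelGrid((2, 1, 1))
    fiber = [np.array([[0.5, 0.5, 0.5], [1.5, 0.5, 0.5]])]
    g = build_direct(fiber, grid)
    vals = compute_visc(g).values.ravel()
    np.testing.assert_array_equal(vals, [0.0, 0.0])


def test_ensure_indirect_caches(worked_example):
    g = build_direct(worked_example.fibers, worked_example.grid)
    y1 = g.ensure_indirect()
    assert g.ensure_indirect() is y1
    assert isinstance(g, ConnectivityGraph)
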