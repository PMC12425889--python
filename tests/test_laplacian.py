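"""Weighted graph construction and the hard-constrained Laplacian solve."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from hbmpose.laplacian import (
    UnconstrainedIslandError,
    build_graph,
    differential_coordinates,
    partition,
    solve_positions,
)
from hbmpose.mesh_io import Element, FEMesh

from .conftest import UNIT_CUBE, make_block_mesh, make_hex_mesh


def two_hex_mesh():
    """Two unit hexes stacked in z, sharing a face (12 nodes)."""
    coords = np.vstack([UNIT_CUBE, UNIT_CUBE[4:] + [0, 0, 1.0]])
    return FEMesh(
        node_ids=np.arange(1, 13),
        coords=coords,
        solids=[
            Element(1, 1, tuple(range(1, 9))),
            Element(2, 1, tuple(range(5, 13))),
        ],
        part_names={1: "stack"},
    )


class TestBuildGraph:
    def test_single_hex_complete_graph(self):
        g = build_graph(make_hex_mesh(UNIT_CUBE))
        assert g.n == 8
        assert all(len(g.neighbors(i)) == 7 for i in range(8))
        assert g.adjacency.nnz == 2 * 28

    def test_weight_formula(self):
        # pair at distance 2 with eps=1e-8 -> w = 1/(8 + 1e-8)
        g = build_graph(make_hex_mesh(UNIT_CUBE * 2.0), epsilon=1e-8)
        assert g.weight(0, 1) == pytest.approx(1.0 / (8.0 + 1e-8), rel=1e-12)

    def test_two_hexes_match_brute_force_pairs(self):
        mesh = two_hex_mesh()
        g = build_graph(mesh)
        expected = set()
        for el in mesh.solids:
            idx = mesh.index_of(el.nodes)
            for a, b in itertools.combinations(sorted(idx), 2):
                expected.add((a, b))
        got = set(
            zip(*sp.triu(g.adjacency, k=1).nonzero())
        )
        assert {(int(a), int(b)) for a, b in got} == expected
        # degrees equal pairwise enumeration
        coords = mesh.coords
        for i in range(g.n):
            di = sum(
                1.0 / (np.linalg.norm(coords[i] - coords[j]) ** 3 + g.epsilon)
                for (a, b) in expected
                for j in ((b,) if a == i else (a,) if b == i else ())
            )
            assert g.degrees[i] == pytest.approx(di, rel=1e-12)

    def test_beams_contribute_edges(self):
        mesh = FEMesh(
            node_ids=np.array([1, 2]),
            coords=np.array([[0.0, 0, 0], [1, 0, 0]]),
            beams=[Element(1, 1, (1, 2))],
        )
        g = build_graph(mesh)
        assert g.adjacency.nnz == 2

    def test_isolated_node_flagged(self):
        mesh = FEMesh(
            node_ids=np.arange(1, 10),
            coords=np.vstack([UNIT_CUBE, [[5.0, 5, 5]]]),
            solids=[Element(1, 1, tuple(range(1, 9)))],
        )
        g = build_graph(mesh)
        assert g.isolated[8] and not g.isolated[:8].any()


class TestDifferentialCoordinates:
    def test_symmetric_node_has_zero_delta(self):
        mesh, ids = make_block_mesh(n=3)
        g = build_graph(mesh)
        delta = differential_coordinates(g, mesh.coords)
        center = mesh.index_of([int(ids[1, 1, 1])])[0]
        np.testing.assert_allclose(delta[center], 0.0, atol=1e-12)

    def test_equals_L_times_V(self):
        mesh = two_hex_mesh()
        g = build_graph(mesh)
        delta = differential_coordinates(g, mesh.coords)
        np.testing.assert_allclose(
            delta, g.laplacian @ mesh.coords, atol=1e-12
        )

    def test_center_node_matches_double_loop(self):
        # independent brute force over the 26 neighbours of the centre
        mesh, ids = make_block_mesh(n=3, spacing=1.3)
        g = build_graph(mesh, epsilon=1e-8)
        delta = differential_coordinates(g, mesh.coords)
        ci = mesh.index_of([int(ids[1, 1, 1])])[0]
        acc = np.zeros(3)
        vi = mesh.coords[ci]
        for j in range(mesh.n_nodes):
            if j == ci:
                continue
            d = np.linalg.norm(vi - mesh.coords[j])
            if d < 1.3 * 1.8:  # all 26 surrounding nodes share an element
                acc += (vi - mesh.coords[j]) / (d**3 + 1e-8)
        np.testing.assert_allclose(delta[ci], acc, rtol=1e-12, atol=1e-12)

    def test_row_sums_zero_and_symmetric(self):
        mesh, _ = make_block_mesh(n=4)
        L = build_graph(mesh).laplacian
        np.testing.assert_allclose(
            np.asarray(L.sum(axis=1)).ravel(), 0.0, atol=1e-10
        )
        assert (L - L.T).nnz == 0 or abs(L - L.T).max() < 1e-14


class TestPartition:
    def test_all_constrained_no_free(self):
        mesh = make_hex_mesh(UNIT_CUBE)
        g = build_graph(mesh)
        sys_ = partition(mesh, g, mesh.node_ids)
        assert sys_.free_idx.size == 0
        out, _ = solve_positions(sys_, mesh.coords)
        np.testing.assert_array_equal(out, mesh.coords)

    def test_single_free_node_reduction(self):
        mesh = make_hex_mesh(UNIT_CUBE)
        g = build_graph(mesh)
        sys_ = partition(mesh, g, mesh.node_ids[1:])
        assert sys_.free_idx.tolist() == [0]
        assert sys_.L_FF.shape == (1, 1)
        assert sys_.L_FF[0, 0] == pytest.approx(g.degrees[0])

    def test_free_count_set_arithmetic(self, small_limb):
        from hbmpose.mesh_io import extract_surface

        mesh = small_limb.mesh
        skin = extract_surface(mesh, {small_limb.parts["skin"]})
        bone = extract_surface(mesh, {small_limb.parts["bone"]})
        cons = np.union1d(skin.node_ids, bone.node_ids)
        g = build_graph(mesh)
        sys_ = partition(mesh, g, cons, on_unanchored="keep")
        n_kept = mesh.n_nodes - sys_.free_idx.size - sys_.fixed_idx.size
        organ_nodes = {
            n for el in mesh.solids if el.pid == small_limb.parts["organ"]
            for n in el.nodes
        }
        assert sys_.fixed_idx.size == cons.size
        assert n_kept == len(organ_nodes)

    def test_unconstrained_island_error_names_part(self, small_limb):
        from hbmpose.mesh_io import extract_surface

        mesh = small_limb.mesh
        skin = extract_surface(mesh, {small_limb.parts["skin"]})
        bone = extract_surface(mesh, {small_limb.parts["bone"]})
        g = build_graph(mesh)
        with pytest.raises(UnconstrainedIslandError, match="organ"):
            partition(mesh, g, np.union1d(skin.node_ids, bone.node_ids))

    def test_L_FF_positive_definite_when_anchored(self):
        mesh, ids = make_block_mesh(n=3)
        g = build_graph(mesh)
        sys_ = partition(mesh, g, [int(ids[0, 0, 0])])
        dense = sys_.L_FF.toarray()
        np.testing.assert_allclose(dense, dense.T, atol=1e-14)
        assert np.linalg.eigvalsh(dense).min() > 0


class TestSolve:
    def test_identity_recovery(self):
        mesh, ids = make_block_mesh(n=4)
        g = build_graph(mesh)
        boundary = [int(i) for i in ids[0].ravel()] + [int(i) for i in ids[-1].ravel()]
        sys_ = partition(mesh, g, np.unique(boundary))
        out, diag = solve_positions(sys_, mesh.coords[sys_.fixed_idx])
        assert np.abs(out - mesh.coords).max() <= 1e-8 * mesh.bbox_diagonal()

    def test_translation_equivariance(self):
        mesh, ids = make_block_mesh(n=4)
        g = build_graph(mesh)
        sys_ = partition(mesh, g, np.unique(ids[0].ravel()))
        t = np.array([3.0, -2.0, 0.5])
        out, _ = solve_positions(sys_, mesh.coords[sys_.fixed_idx] + t)
        np.testing.assert_allclose(out, mesh.coords + t, atol=1e-9)

    def test_scaling_is_not_equivariant(self):
        # weights remember original distances, so uniform scaling of the
        # constraints does NOT scale the free nodes exactly
        mesh, ids = make_block_mesh(n=4, spacing=1.0)
        # break symmetry so the harmonic solution is nontrivial
        rng = np.random.default_rng(0)
        mesh = mesh.with_coords(mesh.coords + rng.normal(0, 0.05, mesh.coords.shape))
        g = build_graph(mesh)
        boundary = np.unique(
            np.concatenate([ids[0].ravel(), ids[-1].ravel(), ids[:, 0].ravel()])
        )
        sys_ = partition(mesh, g, boundary)
        out, _ = solve_positions(sys_, 2.0 * mesh.coords[sys_.fixed_idx])
        assert np.abs(out - 2.0 * mesh.coords).max() > 1e-6

    def test_cg_matches_dense_direct_solve(self):
        mesh, ids = make_block_mesh(n=5)  # 125 nodes
        rng = np.random.default_rng(1)
        g = build_graph(mesh)
        boundary = np.unique(np.concatenate([ids[0].ravel(), ids[-1].ravel()]))
        sys_ = partition(mesh, g, boundary)
        targets = mesh.coords[sys_.fixed_idx] + rng.normal(0, 0.3, (boundary.size, 3))
        out, _ = solve_positions(sys_, targets, tol=1e-12)
        # dense oracle
        A = sys_.L_FF.toarray()
        rhs = sys_.delta[sys_.free_idx] - sys_.L_FC @ targets
        ref = np.linalg.solve(A, rhs)
        assert np.abs(out[sys_.free_idx] - ref).max() <= 1e-8

    def test_normalized_rows_give_same_solution(self):
        # dividing each free row of [L | delta] by deg_i is a row scaling
        # that cannot change the constrained solution
        mesh, ids = make_block_mesh(n=4)
        rng = np.random.default_rng(2)
        g = build_graph(mesh)
        boundary = np.unique(ids[0].ravel())
        sys_ = partition(mesh, g, boundary)
        targets = mesh.coords[sys_.fixed_idx] + rng.normal(0, 0.2, (boundary.size, 3))
        out, _ = solve_positions(sys_, targets, tol=1e-12)
        D = np.diag(1.0 / g.degrees[sys_.free_idx])
        A = D @ sys_.L_FF.toarray()
        rhs = D @ (sys_.delta[sys_.free_idx] - sys_.L_FC @ targets)
        ref = np.linalg.solve(A, rhs)
        assert np.abs(out[sys_.free_idx] - ref).max() <= 1e-8

    def test_harmonic_maximum_principle(self):
        # with delta = 0 each free coordinate is a convex combination of its
        # neighbours, so free values cannot exceed the constrained extremes
        mesh, ids = make_block_mesh(n=5)
        g = build_graph(mesh)
        boundary = np.unique(np.concatenate([ids[0].ravel(), ids[-1].ravel()]))
        sys_ = partition(mesh, g, boundary)
        sys_.delta = np.zeros_like(sys_.delta)
        rng = np.random.default_rng(3)
        targets = rng.uniform(-1, 1, (boundary.size, 3))
        out, _ = solve_positions(sys_, targets, tol=1e-12)
        free_vals = out[sys_.free_idx]
        assert (free_vals.max(axis=0) <= targets.max(axis=0) + 1e-9).all()
        assert (free_vals.min(axis=0) >= targets.min(axis=0) - 1e-9).all()
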