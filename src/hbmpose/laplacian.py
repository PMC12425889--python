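"""Hard-constrained Laplacian deformation of a volumetric FE mesh.

The mesh graph connects every pair of nodes that share an element (solids,
shells and beams all contribute), weighted by the inverse cubic distance in
the *original* mesh:

    w_ij = 1 / (d_ij^3 + eps)

The Laplacian is L = D - A with D the weighted degree matrix, and the
differential coordinates are delta = L V evaluated on the original
coordinates.  Positioning solves, per axis,

    L_FF v_free = delta_free - L_FC c_fixed

with the constrained nodes pinned exactly to their targets.  L_FF is
symmetric positive definite whenever every connected component contains at
least one constrained node, so a Jacobi-preconditioned conjugate-gradient
solve applies; non-convergence falls back to a sparse direct factorisation.

The unnormalised convention (no 1/deg_i row scaling) is used internally:
dividing row i of the square system by deg_i is a positive row scaling that
leaves the constrained solution unchanged but destroys symmetry, so the
symmetric form is the one solved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import cg, splu

from .mesh_io import FEMesh

log = logging.getLogger(__name__)

__all__ = [
    "WeightedGraph",
    "LaplacianSystem",
    "UnconstrainedIslandError",
    "build_graph",
    "differential_coordinates",
    "partition",
    "solve_positions",
]


class UnconstrainedIslandError(ValueError):
    """A connected component of the mesh has no constrained node."""


@dataclass
class WeightedGraph:
    """Element-based weighted adjacency of a mesh.

    ``adjacency`` is the symmetric sparse weight matrix A (w_ij on edges),
    ``degrees`` the per-node weighted degree, ``isolated`` marks nodes that
    belong to no element (excluded from the system, carried through
    unmoved).
    """

    n: int
    adjacency: sp.csr_matrix
    degrees: np.ndarray
    epsilon: float
    isolated: np.ndarray  # bool mask

    def neighbors(self, i: int) -> np.ndarray:
        row = self.adjacency.getrow(i)
        return row.indices

    def weight(self, i: int, j: int) -> float:
        return float(self.adjacency[i, j])

    @property
    def laplacian(self) -> sp.csr_matrix:
        return (sp.diags(self.degrees) - self.adjacency).tocsr()


def build_graph(mesh: FEMesh, epsilon: float = 1e-8) -> WeightedGraph:
    """Weighted adjacency from element co-membership.

    Two nodes are neighbours iff they appear in the same element; the edge
    weight is ``1 / (d^3 + epsilon)`` with ``d`` their Euclidean distance in
    the mesh passed in (the original posture).  Coincident node pairs get
    the finite weight ``1/epsilon`` and are logged as a modelling smell.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n = mesh.n_nodes
    pairs: list[np.ndarray] = []
    for el in mesh.iter_elements():
        idx = mesh.index_of(el.distinct_nodes)
        k = idx.shape[0]
        if k < 2:
            continue
        a, b = np.triu_indices(k, 1)
        pairs.append(np.stack([idx[a], idx[b]], axis=1))
    if not pairs:
        raise ValueError("mesh has no elements")
    edges = np.concatenate(pairs, axis=0)
    edges.sort(axis=1)
    edges = np.unique(edges, axis=0)

    d = np.linalg.norm(mesh.coords[edges[:, 0]] - mesh.coords[edges[:, 1]], axis=1)
    n_coincident = int((d == 0).sum())
    if n_coincident:
        log.warning(
            "%d coincident node pairs share an element (weight 1/epsilon)",
            n_coincident,
        )
    w = 1.0 / (d**3 + epsilon)

    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    A = sp.csr_matrix((np.concatenate([w, w]), (i, j)), shape=(n, n))
    deg = np.asarray(A.sum(axis=1)).ravel()
    isolated = deg == 0
    if isolated.any():
        log.warning(
            "%d isolated node(s) belong to no element; excluded from the system",
            int(isolated.sum()),
        )
    return WeightedGraph(
        n=n, adjacency=A, degrees=deg, epsilon=epsilon, isolated=isolated
    )


def differential_coordinates(
    graph: WeightedGraph, coords: np.ndarray
) -> np.ndarray:
    """delta_i = sum_j w_ij (v_i - v_j), i.e. the rows of L V.

    Isolated nodes get a zero row (they are excluded from any solve).
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape[0] != graph.n:
        raise ValueError("coords length does not match graph")
    return graph.laplacian @ coords


@dataclass
class LaplacianSystem:
    """Partitioned hard-constrained system ready to solve."""

    graph: WeightedGraph
    L: sp.csr_matrix
    delta: np.ndarray
    free_idx: np.ndarray
    fixed_idx: np.ndarray
    coords0: np.ndarray
    blocks: dict = field(default_factory=dict, repr=False)

    @property
    def L_FF(self) -> sp.csr_matrix:
        return self.blocks["FF"]

    @property
    def L_FC(self) -> sp.csr_matrix:
        return self.blocks["FC"]

    @property
    def L_CF(self) -> sp.csr_matrix:
        return self.blocks["CF"]

    @property
    def L_CC(self) -> sp.csr_matrix:
        return self.blocks["CC"]


def _component_part_labels(mesh: FEMesh, comp_nodes: set[int]) -> list[str]:
    ids = {int(mesh.node_ids[i]) for i in comp_nodes}
    labels = set()
    for el in mesh.iter_elements():
        if any(n in ids for n in el.nodes):
            labels.add(mesh.part_names.get(el.pid, f"part_{el.pid}"))
    return sorted(labels)


def partition(
    mesh: FEMesh,
    graph: WeightedGraph,
    constrained_ids,
    coords: np.ndarray | None = None,
    on_unanchored: str = "error",
) -> LaplacianSystem:
    """Split the system into free and constrained nodes.

    Every connected component of the element graph must contain at least one
    constrained node; otherwise its position would be undetermined and an
    :class:`UnconstrainedIslandError` names the offending parts.  With
    ``on_unanchored="keep"`` such components are instead excluded from the
    system and carried through at their original coordinates (useful for
    diagnostic runs that deliberately omit the extra constraints a
    disconnected component would need).  Isolated nodes are placed in
    neither set.
    """
    if on_unanchored not in ("error", "keep"):
        raise ValueError("on_unanchored must be 'error' or 'keep'")
    coords = mesh.coords if coords is None else np.asarray(coords, float)
    cons_idx = mesh.index_of(constrained_ids)
    unknown = set(map(int, constrained_ids)) - set(map(int, mesh.node_ids))
    if unknown:
        raise KeyError(f"constrained IDs not in mesh: {sorted(unknown)[:5]}")

    mask_fixed = np.zeros(graph.n, dtype=bool)
    mask_fixed[cons_idx] = True
    excluded = np.array(graph.isolated)

    n_comp, labels = connected_components(graph.adjacency, directed=False)
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        if graph.isolated[members].all():
            continue
        if not mask_fixed[members].any():
            parts = _component_part_labels(mesh, set(members.tolist()))
            if on_unanchored == "keep":
                log.warning(
                    "unconstrained island (parts: %s) kept at original "
                    "coordinates",
                    ", ".join(parts),
                )
                excluded[members] = True
                continue
            raise UnconstrainedIslandError(
                f"unconstrained island: connected component with "
                f"{members.size} nodes (parts: {', '.join(parts)}) has no "
                f"constrained node"
            )

    free = np.flatnonzero(~mask_fixed & ~excluded)
    fixed = np.flatnonzero(mask_fixed)
    L = graph.laplacian
    delta = differential_coordinates(graph, coords)
    blocks = {
        "FF": L[np.ix_(free, free)].tocsr(),
        "FC": L[np.ix_(free, fixed)].tocsr(),
        "CF": L[np.ix_(fixed, free)].tocsr(),
        "CC": L[np.ix_(fixed, fixed)].tocsr(),
    }
    return LaplacianSystem(
        graph=graph,
        L=L,
        delta=delta,
        free_idx=free,
        fixed_idx=fixed,
        coords0=np.array(coords),
        blocks=blocks,
    )


def solve_positions(
    system: LaplacianSystem,
    fixed_coords: np.ndarray,
    tol: float = 1e-10,
    max_iter: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Solve for the free-node positions given constrained targets.

    ``fixed_coords`` is ``(n_fixed, 3)`` aligned with ``system.fixed_idx``.
    Each axis is solved independently by Jacobi-preconditioned conjugate
    gradients at relative residual ``tol``; on non-convergence the solver
    falls back to a sparse LU factorisation.  Returns the full ``(n, 3)``
    coordinate array (constrained nodes bit-equal to their targets,
    isolated nodes unmoved) plus a diagnostics dict.
    """
    fixed_coords = np.asarray(fixed_coords, dtype=np.float64)
    if fixed_coords.shape != (system.fixed_idx.shape[0], 3):
        raise ValueError("fixed_coords shape mismatch")
    free = system.free_idx
    out = np.array(system.coords0)
    out[system.fixed_idx] = fixed_coords
    diag: dict = {"n_free": int(free.size), "axes": []}
    if free.size == 0:
        return out, diag

    A = system.L_FF
    rhs = system.delta[free] - system.L_FC @ fixed_coords
    if max_iter is None:
        max_iter = max(1000, 10 * free.size)
    d = A.diagonal()
    M = sp.diags(1.0 / d)

    for axis in range(3):
        b = rhs[:, axis]
        n_it = 0

        def cb(_xk):
            nonlocal n_it
            n_it += 1

        x, info = cg(A, b, rtol=tol, atol=0.0, maxiter=max_iter, M=M, callback=cb)
        if info != 0:
            log.warning(
                "CG did not converge on axis %d (info=%d); sparse direct fallback",
                axis,
                info,
            )
            x = splu(A.tocsc()).solve(b)
            n_it = -1
        bn = np.linalg.norm(b)
        res = float(np.linalg.norm(A @ x - b) / bn) if bn > 0 else 0.0
        diag["axes"].append({"iterations": n_it, "relative_residual": res})
        out[free, axis] = x
    return out, diag
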