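"""Boundary-constraint assembly for positioning.

Constraints come in two flavours: ``surface`` entries (skin/skeleton surface
nodes carried to their posed positions) and ``extra`` entries, whose targets
are predicted by local k-nearest-neighbour thin-plate-spline interpolation
from the already-constrained nodes.  Extra constraints are what anchor
topologically disconnected components (organs) and prevent penetration near
large joint rotations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import FEMesh, SurfaceSet, extract_surface
from .tps import ThinPlateSpline, fit_tps

log = logging.getLogger(__name__)

__all__ = [
    "ConstraintSet",
    "ExtraNodeConfig",
    "assemble_surface_constraints",
    "predict_extra_nodes",
    "select_interface_candidates",
    "fit_tps",
    "ThinPlateSpline",
]


@dataclass
class ConstraintSet:
    """Map node ID -> target coordinate, with a provenance tag per entry."""

    entries: dict[int, np.ndarray] = field(default_factory=dict)
    tags: dict[int, str] = field(default_factory=dict)
    sources: dict[int, str] = field(default_factory=dict)

    def add(
        self, node_id: int, target, tag: str = "surface", source: str = ""
    ) -> None:
        target = np.asarray(target, dtype=np.float64)
        if target.shape != (3,) or not np.isfinite(target).all():
            raise ValueError(f"node {node_id}: non-finite or malformed target")
        node_id = int(node_id)
        if node_id in self.entries:
            if not np.allclose(self.entries[node_id], target, atol=1e-6):
                raise ValueError(
                    f"conflicting targets for node {node_id}: "
                    f"{self.entries[node_id]} vs {target}"
                )
            return
        self.entries[node_id] = target
        self.tags[node_id] = tag
        if source:
            self.sources[node_id] = source

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, node_id: int) -> bool:
        return int(node_id) in self.entries

    @property
    def node_ids(self) -> np.ndarray:
        return np.array(sorted(self.entries), dtype=np.int64)

    def targets(self, order: np.ndarray | None = None) -> np.ndarray:
        ids = self.node_ids if order is None else np.asarray(order)
        return np.array([self.entries[int(i)] for i in ids], dtype=np.float64)

    def ids_with_tag(self, tag: str) -> np.ndarray:
        return np.array(
            sorted(i for i, t in self.tags.items() if t == tag), dtype=np.int64
        )

    def validate_against(self, mesh: FEMesh) -> None:
        known = set(map(int, mesh.node_ids))
        missing = [i for i in self.entries if i not in known]
        if missing:
            raise KeyError(f"constraints reference unknown nodes: {missing[:5]}")

    def merged_with(self, other: "ConstraintSet") -> "ConstraintSet":
        out = ConstraintSet(
            dict(self.entries), dict(self.tags), dict(self.sources)
        )
        for nid, tgt in other.entries.items():
            out.add(nid, tgt, other.tags[nid], other.sources.get(nid, ""))
        return out

    # -- file formats -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        data = {
            "constraints": [
                {
                    "node": int(nid),
                    "target": [float(x) for x in self.entries[nid]],
                    "tag": self.tags[nid],
                }
                for nid in sorted(self.entries)
            ]
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConstraintSet":
        data = json.loads(Path(path).read_text())
        out = cls()
        for rec in data["constraints"]:
            out.add(rec["node"], rec["target"], rec.get("tag", "surface"))
        return out


@dataclass
class ExtraNodeConfig:
    """Settings for extra-node target prediction.

    ``k`` nearest already-constrained nodes (in the original posture) feed
    each local TPS fit; at least 5 points are needed for a well-posed
    first-order polynomial part in 3-D.
    """

    k: int = 30
    ridge: float = 0.0
    candidate_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k < 5:
            raise ValueError("k must be >= 5 (affine part needs 4 dof + 1)")


def assemble_surface_constraints(
    mesh: FEMesh,
    posed_surfaces: list[tuple[SurfaceSet, np.ndarray]],
) -> ConstraintSet:
    """One ``surface`` entry per surface node, target = posed coordinate.

    Each posed coordinate array aligns index-wise with its surface's sorted
    ``node_ids`` (the OBJ sidecar order).  Nodes shared between surfaces
    must agree to 1e-6 or the assembly fails listing the offenders.
    """
    cs = ConstraintSet()
    for surf, posed in posed_surfaces:
        posed = np.asarray(posed, dtype=np.float64)
        if posed.shape != (surf.n_nodes, 3):
            raise ValueError(
                f"surface '{surf.name}': posed coords shape {posed.shape} "
                f"does not match {surf.n_nodes} nodes"
            )
        conflicts = []
        for nid, tgt in zip(surf.node_ids, posed):
            try:
                cs.add(int(nid), tgt, tag="surface", source=surf.name)
            except ValueError:
                conflicts.append(int(nid))
        if conflicts:
            raise ValueError(
                f"surface '{surf.name}': conflicting duplicate targets for "
                f"nodes {conflicts[:10]}"
            )
    cs.validate_against(mesh)
    return cs


def predict_extra_nodes(
    mesh: FEMesh,
    constraints: ConstraintSet,
    config: ExtraNodeConfig,
) -> ConstraintSet:
    """Predict targets for extra constrained nodes by local k-NN TPS.

    For each candidate, its ``k`` nearest already-constrained nodes are
    found in the *original* coordinates via a KD-tree; a local TPS fitted
    from their original -> target positions is evaluated at the candidate's
    original position.  Returns the input set extended with ``extra``
    entries (candidates already constrained are skipped).
    """
    if len(constraints) == 0:
        raise ValueError("no constraints to interpolate from")
    if config.candidate_ids is None or len(config.candidate_ids) == 0:
        return constraints

    cons_ids = constraints.node_ids
    cons_orig = mesh.coords[mesh.index_of(cons_ids)]
    cons_tgt = constraints.targets(cons_ids)
    k = config.k
    if k > cons_ids.size:
        log.warning(
            "only %d constrained nodes available; using all of them (k=%d)",
            cons_ids.size,
            k,
        )
        k = cons_ids.size
        if k < 5:
            raise ValueError("fewer than 5 constrained nodes; cannot fit TPS")

    tree = cKDTree(cons_orig)
    out = constraints.merged_with(ConstraintSet())
    cand = [int(c) for c in config.candidate_ids if int(c) not in constraints]
    if not cand:
        return out
    q = mesh.coords[mesh.index_of(cand)]
    _, nn = tree.query(q, k=k)
    nn = np.atleast_2d(nn)
    for row, (nid, x) in enumerate(zip(cand, q)):
        idx = nn[row]
        model = fit_tps(cons_orig[idx], cons_tgt[idx], ridge=config.ridge)
        pred = model(x)
        out.add(nid, pred, tag="extra", source=f"tps_k{k}")
    return out


# ---------------------------------------------------------------------------
# interface candidate selection (advisory)
# ---------------------------------------------------------------------------


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distances from points ``(n, 3)`` to one triangle ``(3, 3)``."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d1 = ap @ ab
    d2 = ap @ ac
    bp = p - b
    d3 = bp @ ab
    d4 = bp @ ac
    cp = p - c
    d5 = cp @ ab
    d6 = cp @ ac
    nn = np.cross(ab, ac)

    # barycentric region tests (Ericson, real-time collision detection)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    proj = a + np.outer(v, ab) + np.outer(w, ac)

    def seg_dist(p, s0, s1):
        d = s1 - s0
        t = np.clip((p - s0) @ d / max(d @ d, 1e-300), 0.0, 1.0)
        return np.linalg.norm(p - (s0 + np.outer(t, d)), axis=1)

    dist = np.linalg.norm(p - proj, axis=1)
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)
    if (~inside).any():
        edge = np.minimum.reduce(
            [seg_dist(p, a, b), seg_dist(p, b, c), seg_dist(p, a, c)]
        )
        dist = np.where(inside, dist, edge)
    _ = nn, d1, d2  # kept for clarity of the construction
    return dist


def distance_to_surface(
    points: np.ndarray, surface: SurfaceSet, mesh: FEMesh
) -> np.ndarray:
    """Min distance from each point to the (triangulated) surface faces."""
    points = np.asarray(points, dtype=np.float64)
    coords = {int(n): mesh.coords[mesh.index_of([n])[0]] for n in surface.node_ids}
    tris = []
    for f in surface.faces:
        pts = [coords[int(n)] for n in f]
        for k in range(1, len(pts) - 1):
            tris.append((pts[0], pts[k], pts[k + 1]))
    dmin = np.full(points.shape[0], np.inf)
    # prune with a KD-tree on face vertices: exact distance only for faces
    # whose vertices come within reach of the current bound
    verts = np.array([coords[int(n)] for n in surface.node_ids])
    tree = cKDTree(verts)
    d_vert, _ = tree.query(points)
    for tri in tris:
        tri = np.asarray(tri)
        # cheap bound: skip points farther from tri centroid than bound+radius
        cen = tri.mean(axis=0)
        rad = np.linalg.norm(tri - cen, axis=1).max()
        near = np.linalg.norm(points - cen, axis=1) - rad < dmin
        if near.any():
            dmin[near] = np.minimum(
                dmin[near], _point_triangle_distance(points[near], tri)
            )
    return np.minimum(dmin, d_vert)


def select_interface_candidates(
    mesh: FEMesh,
    part_a: int | set[int],
    part_b: int | set[int],
    threshold: float,
) -> np.ndarray:
    """Nodes of part group A within ``threshold`` of part group B's surface.

    Advisory helper for picking extra constrained nodes at anatomical
    interfaces; the returned IDs are meant for user review.  Distances are
    evaluated in the original mesh.  An empty result is allowed.
    """
    a = {part_a} if np.isscalar(part_a) else set(part_a)
    b = {part_b} if np.isscalar(part_b) else set(part_b)
    ids_a = sorted(
        {n for el in mesh.iter_elements() if el.pid in a for n in el.nodes}
    )
    if not ids_a:
        raise KeyError(f"no elements found for part(s) {sorted(a)}")
    ids_a = np.array(ids_a, dtype=np.int64)
    if threshold <= 0:
        return np.array([], dtype=np.int64)
    if np.isinf(threshold):
        return ids_a
    surf_b = extract_surface(mesh, b, name="B")
    pts = mesh.coords[mesh.index_of(ids_a)]
    d = distance_to_surface(pts, surf_b, mesh)
    return ids_a[d <= threshold]
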