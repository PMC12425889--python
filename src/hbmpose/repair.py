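"""Post-positioning mesh repair driven by TPS mapping of original geometry.

Elements whose scaled Jacobian falls below a threshold in the positioned
mesh are *distorted*.  Their nodes become *defective*; the remaining nodes
of the distorted elements' neighbouring elements (sharing at least one
node) become *reference* nodes.  Per node-connected cluster of distorted
elements, a TPS is fitted from the reference nodes' original positions to
their positioned positions, and each defective node is re-placed by
evaluating that map at its original position — transplanting the original
local spatial relationships into the positioned state.

Constrained (boundary) nodes are never moved: if one lands in a distorted
element it is reclassified as a reference node, because the boundary
constraints define the posture and must win over element quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mesh_io import FEMesh
from .quality import QualityReport, quality_report
from .tps import fit_tps

log = logging.getLogger(__name__)

__all__ = [
    "RepairCluster",
    "RepairPlan",
    "build_repair_plan",
    "repair_nodes",
    "repair_until_stable",
]

MIN_REFERENCE_NODES = 5  # TPS needs >= 5 points for its affine part
MAX_NEIGHBOR_RINGS = 3


@dataclass
class RepairCluster:
    """One node-connected group of distorted elements."""

    element_keys: list[tuple[str, int]]  # (kind, eid)
    defective_nodes: set[int]
    reference_nodes: set[int]
    rings_used: int = 1
    repairable: bool = True


@dataclass
class RepairPlan:
    distorted_elements: list[tuple[str, int]]
    defective_nodes: set[int]
    reference_nodes: set[int]
    clusters: list[RepairCluster] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.distorted_elements


def _element_entries(mesh: FEMesh):
    """(kind, eid, node-id tuple) for solids then shells, report order."""
    out = []
    for el in mesh.solids:
        out.append(("solid", el.eid, el.distinct_nodes))
    for el in mesh.shells:
        out.append(("shell", el.eid, el.distinct_nodes))
    return out


def build_repair_plan(
    positioned_mesh: FEMesh,
    quality: QualityReport,
    j_threshold: float = 0.3,
    protected_node_ids=None,
) -> RepairPlan:
    """Classify defective/reference nodes around the distorted elements.

    ``quality`` must have been computed on the positioned mesh; the report
    order (solids then shells) is relied upon.  ``protected_node_ids``
    (typically the constrained boundary nodes) are reclassified from
    defective to reference.
    """
    entries = _element_entries(positioned_mesh)
    if len(entries) != quality.jacobian.size:
        raise ValueError("quality report does not match mesh element count")
    protected = (
        set() if protected_node_ids is None else set(map(int, protected_node_ids))
    )

    distorted_idx = np.flatnonzero(quality.jacobian < j_threshold)
    distorted = [entries[k][:2] for k in distorted_idx]
    if not distorted_idx.size:
        return RepairPlan([], set(), set(), [])

    node_to_elems: dict[int, list[int]] = {}
    for k, (_, _, nodes) in enumerate(entries):
        for n in nodes:
            node_to_elems.setdefault(n, []).append(k)

    # cluster distorted elements by shared nodes (union-find)
    parent = {int(k): int(k) for k in distorted_idx}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    dist_set = set(map(int, distorted_idx))
    for k in distorted_idx:
        for n in entries[k][2]:
            for other in node_to_elems[n]:
                if other in dist_set:
                    union(int(k), other)

    groups: dict[int, list[int]] = {}
    for k in dist_set:
        groups.setdefault(find(k), []).append(k)

    all_defective: set[int] = set()
    for members in groups.values():
        for k in members:
            all_defective.update(entries[k][2])
    all_defective -= protected

    clusters: list[RepairCluster] = []
    for members in groups.values():
        defective = set()
        for k in members:
            defective.update(entries[k][2])
        defective -= protected

        ring_elems = set(members)
        reference: set[int] = set()
        rings = 0
        while rings < MAX_NEIGHBOR_RINGS:
            rings += 1
            frontier_nodes = set()
            for k in ring_elems:
                frontier_nodes.update(entries[k][2])
            grown = set(ring_elems)
            for n in frontier_nodes:
                grown.update(node_to_elems[n])
            ring_elems = grown
            reference = set()
            for k in ring_elems:
                reference.update(entries[k][2])
            reference -= all_defective
            if len(reference) >= MIN_REFERENCE_NODES:
                break
        repairable = len(reference) >= MIN_REFERENCE_NODES and bool(defective)
        if not repairable:
            log.warning(
                "cluster of %d distorted element(s) unrepairable "
                "(%d reference nodes after %d rings)",
                len(members),
                len(reference),
                rings,
            )
        clusters.append(
            RepairCluster(
                element_keys=[entries[k][:2] for k in sorted(members)],
                defective_nodes=defective,
                reference_nodes=reference,
                rings_used=rings,
                repairable=repairable,
            )
        )

    all_reference = set()
    for c in clusters:
        all_reference |= c.reference_nodes
    all_reference -= all_defective
    return RepairPlan(
        distorted_elements=distorted,
        defective_nodes=all_defective,
        reference_nodes=all_reference,
        clusters=clusters,
    )


def repair_nodes(
    original_mesh: FEMesh,
    positioned_coords: np.ndarray,
    plan: RepairPlan,
    ridge: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Re-place defective nodes via per-cluster TPS maps.

    For each repairable cluster a TPS is fitted from the reference nodes'
    original positions to their positioned positions and evaluated at the
    defective nodes' original positions.  All other nodes are returned
    bit-identical.
    """
    coords = np.array(positioned_coords, dtype=np.float64)
    info = {"clusters": len(plan.clusters), "skipped": 0, "moved_nodes": 0}
    if plan.is_empty:
        return coords, info
    for cluster in plan.clusters:
        if not cluster.repairable:
            info["skipped"] += 1
            continue
        ref = sorted(cluster.reference_nodes)
        bad = sorted(cluster.defective_nodes)
        if not bad:
            continue
        ref_idx = original_mesh.index_of(ref)
        bad_idx = original_mesh.index_of(bad)
        try:
            model = fit_tps(
                original_mesh.coords[ref_idx], coords[ref_idx], ridge=ridge
            )
        except Exception as exc:  # singular after ridge bump
            log.warning("cluster skipped: TPS fit failed (%s)", exc)
            info["skipped"] += 1
            continue
        coords[bad_idx] = model(original_mesh.coords[bad_idx])
        info["moved_nodes"] += len(bad)
    return coords, info


def repair_until_stable(
    original_mesh: FEMesh,
    positioned_coords: np.ndarray,
    j_threshold: float = 0.3,
    max_passes: int = 5,
    protected_node_ids=None,
    ridge: float = 0.0,
) -> tuple[np.ndarray, list[dict]]:
    """Iterate quality -> plan -> repair while quality improves.

    A pass is accepted when the pair (distorted count, negative-volume
    count) does not worsen in either component and strictly improves in at
    least one; the first rejected pass ends the iteration and the best
    accepted coordinates are returned, together with a per-pass log of the
    three quality counts.
    """
    if max_passes < 1:
        raise ValueError("max_passes must be >= 1")
    best = np.array(positioned_coords, dtype=np.float64)
    rep = quality_report(original_mesh, coords=best, j_threshold=j_threshold)

    def score(r: QualityReport) -> tuple[int, int]:
        return (r.n_j_below(j_threshold), r.n_negative_volume)

    best_score = score(rep)
    passes = [
        {
            "pass": 0,
            "n_J_below": best_score[0],
            "n_negative_volume": best_score[1],
            "n_AR_above": rep.n_ar_above(),
            "moved_nodes": 0,
        }
    ]
    for p in range(1, max_passes + 1):
        plan = build_repair_plan(
            original_mesh.with_coords(best),
            rep,
            j_threshold=j_threshold,
            protected_node_ids=protected_node_ids,
        )
        if plan.is_empty or not plan.defective_nodes:
            break
        trial, info = repair_nodes(original_mesh, best, plan, ridge=ridge)
        trial_rep = quality_report(
            original_mesh, coords=trial, j_threshold=j_threshold
        )
        s = score(trial_rep)
        passes.append(
            {
                "pass": p,
                "n_J_below": s[0],
                "n_negative_volume": s[1],
                "n_AR_above": trial_rep.n_ar_above(),
                "moved_nodes": info["moved_nodes"],
            }
        )
        improved = s[0] <= best_score[0] and s[1] <= best_score[1] and s < best_score
        if not improved:
            passes[-1]["rejected"] = True
            break
        best, best_score, rep = trial, s, trial_rep
        if best_score == (0, 0):
            break
    return best, passes
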