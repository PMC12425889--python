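"""Three-stage positioning pipeline: constraints -> Laplacian -> repair.

``position_mesh`` is the library workhorse: given a mesh and a constraint
set it builds the weighted graph, solves the hard-constrained system,
assesses quality and repairs distorted elements.  ``position_limb`` runs
the complete synthetic-limb study (pose generation, surface constraints,
optional TPS-predicted extra constraints, penetration accounting) and is
what the bundled examples and validation scripts call.  ``run_position``
is the file-driven entry point behind the command line.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constraints import (
    ConstraintSet,
    ExtraNodeConfig,
    assemble_surface_constraints,
    predict_extra_nodes,
)
from .fixtures import (
    LimbFixture,
    LimbFixtureSpec,
    count_penetrations,
    generate_limb,
)
from .laplacian import build_graph, partition, solve_positions
from .mesh_io import (
    FEMesh,
    SurfaceSet,
    extract_surface,
    read_keyword_mesh,
    read_obj_vertices,
    write_keyword_mesh,
)
from .quality import quality_report
from .repair import repair_until_stable

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PositionResult",
    "position_mesh",
    "position_limb",
    "run_position",
]


@dataclass
class PositionResult:
    """Everything a positioning run produces."""

    coords: np.ndarray
    coords_unrepaired: np.ndarray
    constraints: ConstraintSet
    solver: dict
    quality_before: dict
    quality_after_laplacian: dict
    quality_after_repair: dict
    repair_passes: list[dict]
    timings: dict = field(default_factory=dict)

    def report(self) -> dict:
        return {
            "solver": self.solver,
            "n_constraints": len(self.constraints),
            "quality": {
                "original": self.quality_before,
                "after_laplacian": self.quality_after_laplacian,
                "after_repair": self.quality_after_repair,
            },
            "repair_passes": self.repair_passes,
            "timings": self.timings,
        }


def position_mesh(
    mesh: FEMesh,
    constraints: ConstraintSet,
    epsilon: float = 1e-8,
    tol: float = 1e-10,
    max_iter: int | None = None,
    j_threshold: float = 0.3,
    ar_threshold: float = 10.0,
    repair_passes: int = 3,
    do_repair: bool = True,
    on_unanchored: str = "error",
) -> PositionResult:
    """Hard-constrained Laplacian positioning with post-repair."""
    constraints.validate_against(mesh)
    t0 = time.perf_counter()
    graph = build_graph(mesh, epsilon=epsilon)
    system = partition(
        mesh, graph, constraints.node_ids, on_unanchored=on_unanchored
    )
    targets = constraints.targets(
        np.array([int(mesh.node_ids[i]) for i in system.fixed_idx])
    )
    t1 = time.perf_counter()
    coords, solver_diag = solve_positions(
        system, targets, tol=tol, max_iter=max_iter
    )
    t2 = time.perf_counter()

    q0 = quality_report(
        mesh, j_threshold=j_threshold, ar_threshold=ar_threshold
    ).summary()
    q1 = quality_report(
        mesh, coords=coords, j_threshold=j_threshold, ar_threshold=ar_threshold
    ).summary()
    if do_repair:
        repaired, passes = repair_until_stable(
            mesh,
            coords,
            j_threshold=j_threshold,
            max_passes=repair_passes,
            protected_node_ids=constraints.node_ids,
        )
    else:
        repaired, passes = coords, []
    q2 = quality_report(
        mesh,
        coords=repaired,
        j_threshold=j_threshold,
        ar_threshold=ar_threshold,
    ).summary()
    t3 = time.perf_counter()
    return PositionResult(
        coords=repaired,
        coords_unrepaired=coords,
        constraints=constraints,
        solver=solver_diag,
        quality_before=q0,
        quality_after_laplacian=q1,
        quality_after_repair=q2,
        repair_passes=passes,
        timings={
            "build_s": t1 - t0,
            "solve_s": t2 - t1,
            "quality_repair_s": t3 - t2,
        },
    )


# ---------------------------------------------------------------------------
# synthetic-limb study
# ---------------------------------------------------------------------------


def _limb_surface_constraints(
    fixture: LimbFixture, posed: np.ndarray
) -> ConstraintSet:
    mesh = fixture.mesh
    surfaces = []
    for name in ("skin", "bone"):
        surf = extract_surface(mesh, {fixture.parts[name]}, name=name)
        idx = mesh.index_of(surf.node_ids)
        surfaces.append((surf, posed[idx]))
    return assemble_surface_constraints(mesh, surfaces)


def limb_penetration_counts(
    fixture: LimbFixture, coords: np.ndarray, seed: int = 0
) -> dict:
    """Wrong-side counts for the limb's free interface nodes.

    Checks the flesh inner surface and (if present) the organ against the
    closed skin envelope (must stay inside) and the bone surface (must stay
    outside).
    """
    mesh = fixture.mesh
    skin_surf = fixture.closed_skin_surface()
    skin_xyz = coords[mesh.index_of(skin_surf.node_ids)]
    bone_surf = extract_surface(mesh, {fixture.parts["bone"]}, name="bone")
    bone_xyz = coords[mesh.index_of(bone_surf.node_ids)]

    probes = {"flesh_inner": fixture.interface_ids["flesh_inner"]}
    if "organ_surface" in fixture.interface_ids:
        probes["organ"] = fixture.interface_ids["organ_surface"]

    out: dict = {}
    total = 0
    for name, ids in probes.items():
        pts = coords[mesh.index_of(ids)]
        esc = count_penetrations(pts, (skin_surf, skin_xyz), "outside", seed)
        swal = count_penetrations(pts, (bone_surf, bone_xyz), "inside", seed)
        out[f"{name}_outside_skin"] = esc
        out[f"{name}_inside_bone"] = swal
        total += esc + swal
    out["total"] = total
    return out


def position_limb(
    fixture: LimbFixture | None = None,
    angle_deg: float = 90.0,
    with_extras: bool = True,
    k: int = 100,
    epsilon: float = 1e-8,
    tol: float = 1e-10,
    j_threshold: float = 0.3,
    repair_passes: int = 8,
    do_repair: bool = True,
    on_unanchored: str | None = None,
    seed: int = 0,
) -> tuple[PositionResult, dict]:
    """End-to-end limb bend: pose, constrain, solve, repair, validate.

    With ``with_extras`` the recorded interface candidates (flesh inner
    surface near the joint, plus the organ boundary) receive TPS-predicted
    targets before the solve.  Returns the positioning result and the
    penetration counts measured on the final coordinates.

    The organ is a disconnected component reachable only through extra
    constraints; without them it is carried through unmoved (and is then
    left behind by the bend — the penetration the extra constraints exist
    to prevent).  ``k`` defaults to a neighbourhood of ~3 rings of surface
    nodes at the default fixture density.
    """
    if fixture is None:
        fixture = generate_limb(LimbFixtureSpec(seed=seed))
    posed = fixture.posed_coords(angle_deg)
    cs = _limb_surface_constraints(fixture, posed)
    if with_extras:
        cand = [fixture.interface_ids["joint"], fixture.interface_ids["ends"]]
        if "organ_surface" in fixture.interface_ids:
            cand.append(fixture.interface_ids["organ_surface"])
        cfg = ExtraNodeConfig(
            k=k, candidate_ids=np.concatenate(cand)
        )
        cs = predict_extra_nodes(fixture.mesh, cs, cfg)
    if on_unanchored is None:
        # a run that skips the extra constraints cannot anchor the organ;
        # keep such components in place instead of refusing to run
        on_unanchored = "error" if with_extras else "keep"
    result = position_mesh(
        fixture.mesh,
        cs,
        epsilon=epsilon,
        tol=tol,
        j_threshold=j_threshold,
        repair_passes=repair_passes,
        do_repair=do_repair,
        on_unanchored=on_unanchored,
    )
    pens = limb_penetration_counts(fixture, result.coords, seed=seed)
    return result, pens


# ---------------------------------------------------------------------------
# file-driven runs
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Archivable configuration for a positioning run."""

    mesh_path: str = ""
    skin_parts: list[int] = field(default_factory=list)
    skeleton_parts: list[int] = field(default_factory=list)
    posed_skin_obj: str = ""
    posed_skeleton_obj: str = ""
    extra_ids_path: str = ""
    constraints_json: str = ""
    k: int = 30
    epsilon: float = 1e-8
    tol: float = 1e-10
    max_iter: int | None = None
    j_threshold: float = 0.3
    ar_threshold: float = 10.0
    repair_max_passes: int = 3
    out_dir: str = "positioned"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.j_threshold <= 0 or self.ar_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__))


def _posed_surface(
    mesh: FEMesh, parts: list[int], obj_path: str, name: str
) -> tuple[SurfaceSet, np.ndarray]:
    surf = extract_surface(mesh, set(parts), name=name)
    posed = read_obj_vertices(obj_path)
    sidecar = Path(obj_path).with_suffix(Path(obj_path).suffix + ".map.json")
    if sidecar.exists():
        order = json.loads(sidecar.read_text())["obj_to_node"]
        lookup = {int(n): k for k, n in enumerate(order)}
        posed = posed[[lookup[int(n)] for n in surf.node_ids]]
    elif posed.shape[0] != surf.n_nodes:
        raise ValueError(
            f"{obj_path}: vertex count {posed.shape[0]} != surface node "
            f"count {surf.n_nodes} and no sidecar map found"
        )
    return surf, posed


def run_position(config: RunConfig) -> PositionResult:
    """Execute a configured run and write its artifacts.

    Outputs in ``config.out_dir``: the positioned keyword mesh, quality CSVs
    before/after, and a JSON run report.  A stage failure raises with a
    stage-labelled message after writing partial artifacts to
    ``<out_dir>/quarantine``.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "read mesh"
    try:
        mesh = read_keyword_mesh(config.mesh_path)

        stage = "assemble constraints"
        if config.constraints_json:
            cs = ConstraintSet.from_json(config.constraints_json)
            cs.validate_against(mesh)
        else:
            posed = []
            if config.skin_parts:
                posed.append(
                    _posed_surface(
                        mesh, config.skin_parts, config.posed_skin_obj, "skin"
                    )
                )
            if config.skeleton_parts:
                posed.append(
                    _posed_surface(
                        mesh,
                        config.skeleton_parts,
                        config.posed_skeleton_obj,
                        "skeleton",
                    )
                )
            cs = assemble_surface_constraints(mesh, posed)

        stage = "predict extra nodes"
        if config.extra_ids_path:
            ids = [
                int(tok)
                for tok in Path(config.extra_ids_path).read_text().split()
            ]
            cs = predict_extra_nodes(
                mesh, cs, ExtraNodeConfig(k=config.k, candidate_ids=ids)
            )

        stage = "laplacian solve + repair"
        result = position_mesh(
            mesh,
            cs,
            epsilon=config.epsilon,
            tol=config.tol,
            max_iter=config.max_iter,
            j_threshold=config.j_threshold,
            ar_threshold=config.ar_threshold,
            repair_passes=config.repair_max_passes,
        )

        stage = "write outputs"
        write_keyword_mesh(
            mesh.with_coords(result.coords), out_dir / "positioned.k"
        )
        quality_report(
            mesh,
            coords=result.coords_unrepaired,
            j_threshold=config.j_threshold,
            ar_threshold=config.ar_threshold,
            csv_path=out_dir / "quality_after_laplacian.csv",
        )
        quality_report(
            mesh,
            coords=result.coords,
            j_threshold=config.j_threshold,
            ar_threshold=config.ar_threshold,
            csv_path=out_dir / "quality_after_repair.csv",
        )
        (out_dir / "run_report.json").write_text(
            json.dumps(result.report(), indent=1, default=float)
        )
        return result
    except Exception as exc:
        q = out_dir / "quarantine"
        q.mkdir(parents=True, exist_ok=True)
        (q / "failure.json").write_text(
            json.dumps({"stage": stage, "error": str(exc)})
        )
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
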