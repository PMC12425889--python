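"""Hard-constrained Laplacian positioning of a bent limb.

Skin and bone surface nodes are posed by the armature (linear blend
skinning) and enforced exactly; every interior node is solved from the
preserved differential coordinates.
"""

import numpy as np

from hbmpose import (
    LimbFixtureSpec,
    assemble_surface_constraints,
    build_graph,
    extract_surface,
    generate_limb,
    partition,
    solve_positions,
)

fixture = generate_limb(LimbFixtureSpec())
mesh = fixture.mesh
posed = fixture.posed_coords(45.0)

surfaces = []
for name in ("skin", "bone"):
    surf = extract_surface(mesh, {fixture.parts[name]}, name=name)
    surfaces.append((surf, posed[mesh.index_of(surf.node_ids)]))
constraints = assemble_surface_constraints(mesh, surfaces)

graph = build_graph(mesh, epsilon=1e-8)
# the organ has no surface constraints here; keep it in place for the demo
system = partition(mesh, graph, constraints.node_ids, on_unanchored="keep")
coords, diag = solve_positions(
    system, constraints.targets(mesh.node_ids[system.fixed_idx])
)

moved = np.linalg.norm(coords - mesh.coords, axis=1)
print(f"constrained nodes: {len(constraints)}   free: {system.free_idx.size}")
for ax in diag["axes"]:
    print(f"  CG iterations {ax['iterations']}, residual {ax['relative_residual']:.1e}")
print(f"max node displacement: {moved.max():.1f} mm (45 degree bend)")
# Constrained nodes land exactly on their targets; the interior follows
# smoothly because its differential coordinates are preserved.
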