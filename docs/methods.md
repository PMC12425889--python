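# Methods

## Model and assumptions

Positioning is posed as a boundary-value problem on the element graph of a
volumetric FE mesh. The core assumption is that a node's *differential
coordinates* — `delta_i = sum_j w_ij (v_i - v_j)` over its element
neighbours — change little between postures, so enforcing posed surface
positions exactly while preserving `delta` for the interior yields a
smooth, locally shape-preserving deformation. This assumption degrades
precisely where large joint rotations change local geometry nonlinearly,
and it carries no notion of contact between topologically disconnected
parts; both weaknesses are addressed by *extra constrained nodes* rather
than by altering the operator.

Element-based adjacency (all node pairs within any solid, shell or beam)
rather than face or edge adjacency keeps the operator faithful to the
model's full topological structure. Weights use the inverse cubic distance
`w_ij = 1/(d_ij^3 + eps)` measured in the original mesh, so near pairs
dominate; coincident nodes receive the finite weight `1/eps` and are
logged as a modelling smell.

### Normalisation convention

The degree-normalised form of the differential coordinates (each row of
`[L | delta]` divided by `deg_i`) and the unnormalised form `L = D - A`
differ by a positive row scaling, which cannot change the solution of the
square constrained system. The package uses the unnormalised, symmetric
form internally so that plain conjugate gradients applies, and asserts the
equivalence numerically in the test suite (solutions agree to solver
tolerance).

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `epsilon` | 1e-8 | mesh-length^3 | guards the weight denominator; any small positive value works, it only matters for coincident nodes |
| CG `tol` | 1e-10 | relative residual | per-axis; 1e-13 is used when verifying exact algebraic properties (identity, translation) |
| CG `max_iter` | 10·n_free | — | non-convergence falls back to sparse LU and is logged |
| TPS `ridge` | 0 | length² | exact interpolation; automatic bump to `1e-10·(mean pairwise distance)²` on a singular/unreliable fit |
| extra-node `k` | 30 | neighbours | minimum 5 (affine part needs 4 dof); see below |
| `J` threshold | 0.3 | — | distorted-element cutoff, standard pre-processor practice |
| `AR` threshold | 10 | — | stretched-element cutoff |
| repair `max_passes` | 5 | — | iteration is an engineering extension; a pass is kept only if the pair (J<0.3 count, J<0 count) does not worsen and improves somewhere |

### Choice of k

The k nearest *constrained* nodes are searched in the original
coordinates. Near a joint the pool is one-sided — the nearest constrained
nodes are all skin — and a very local TPS extrapolates poorly toward the
interior. `k` should therefore cover a patch a few node-rings wide at the
mesh's surface density: the limb study uses `k = 100` (≈3 rings at the
default fixture density), which reduced the worst-case deviation of
predictions from the skinning ground truth from ~5.8 mm (`k = 30`) to
~2 mm. The module default stays at 30, appropriate for coarser meshes.

## Quality metric conventions

"Scaled Jacobian" follows the corner convention used by solver
pre-processors: at each hex corner, the determinant of the three emanating
edge vectors normalised to unit length; the element value is the minimum
corner value, giving `J ∈ [-1, 1]` with 1 for a cube and negative values
for inverted elements. Tetrahedra are normalised by `sqrt(2)/2` (regular
tet → 1), triangles by `sqrt(3)/2` (equilateral → 1); quads use the corner
cross-product against the element normal. Aspect ratio is the plain
longest/shortest edge ratio — the simplest convention consistent with
"relative stretching"; radius-based alternatives were rejected as opaque.
Collapsed (degenerate) solid records are evaluated on their distinct
corners only. Beams carry neutral values and never enter the counts.
Because the convention is not universal across pre-processors, absolute
counts are comparable only within one convention.

## Repair

Distorted elements (`J` below threshold in the positioned mesh) are
clustered by shared nodes. Per cluster, defective nodes (nodes of the
distorted elements) are re-placed by a TPS fitted from the reference
nodes' original positions to their positioned positions — reference nodes
being the remaining nodes of the distorted-plus-neighbouring elements,
grown by up to three element rings if fewer than five are available
(fewer than five leaves the cluster unrepairable, reported). Two rules
beyond the basic scheme:

* **Boundary fidelity beats element quality.** Constrained nodes are never
  moved; if one lies in a distorted element it is reclassified as a
  reference node. The posture definition must win.
* **Accept-only-improvement iteration.** Repair can migrate distortion
  into marginal neighbours; passes iterate only while the pair
  (J<0.3 count, negative count) improves componentwise, and the best
  accepted state is returned. A single pass reproduces the non-iterated
  behaviour.

## The synthetic limb: what it emulates, what it does not

The generator builds a two-segment limb (default ~15.4k elements / ~17.3k
nodes, mm units): hollow cortical **bone** tubes (radius 6–10 mm) per
segment, disconnected across the joint; a **flesh** hex annulus
(14–25 mm) running the full length; a **skin** quad shell sharing the
flesh's outer nodes; and a 3 mm **organ** cube resting 0.5 mm from the
distal bone — anatomically adjacent, topologically disconnected. A
one-hinge armature with linear blend skinning (LBS) produces target
postures: bone and organ bind rigidly to their segment, flesh and skin
blend across a transition band around the joint.

Deliberate design choices:

* **LBS, not dual-quaternion skinning** — its candy-wrapper pinching at
  the joint generates exactly the element distortions the repair stage
  exists for.
* **Transition band 90 mm** (≈1.8 limb diameters for the 90° study bend).
  The band is the knob that sets how hard the joint region is stressed;
  below ~80 mm the *skinned target itself* contains inverted elements —
  an unrealizable target posture that no constraint-respecting solve or
  repair could fix, and which a curated skinning setup (manual weight
  painting) would never produce. 90 mm keeps the target volume-positive
  with margin while still pinching hard enough to distort >100 elements.
* **Joint gap 25 mm** keeps the rigid bone tips clear of the flexion
  crease of the blended skin.
* **Organ on the distal side of the joint**, so a run without extra
  constraints (which keeps unanchorable components in place) leaves it
  behind as the limb bends away — the canonical disconnected-component
  penetration.
* **Open end planes** are a fixture artifact (real HBMs are closed); they
  drift under rotation because differential coordinates are not
  rotation-invariant, so the generator records the end-plane flesh nodes
  as standard extra-constraint candidates alongside the joint interface
  and organ boundary.

What passing the limb study does **not** show about real HBMs: anatomical
heterogeneity (muscle/fat layering, ligaments, contact-calibrated gaps),
multi-joint kinematic chains, meshes with mixed tet/hex transitions, and
production-scale conditioning (10^6+ nodes). The fixture demonstrates the
mechanisms — constraint propagation, disconnected-component anchoring,
fold-induced distortion and its repair — not anatomical fidelity.

## Numerical choices and degenerate inputs

* Per-axis CG with Jacobi preconditioning on the SPD block; deterministic
  for a fixed mesh and ordering, which is what makes configured runs
  bitwise reproducible.
* Every connected component must contain a constrained node, else the
  block is singular: a hard "unconstrained island" error naming the parts.
  `on_unanchored="keep"` opts into carrying such components unmoved — used
  by the diagnostic "without extra constraints" comparison and for nothing
  else.
* Isolated nodes (no element membership) are excluded from the system and
  carried through unchanged, with a warning.
* TPS systems are solved directly; a fit that fails to reproduce its own
  controls triggers the ridge bump, then a least-squares fallback.
* Point-in-polyhedron testing fires three independent random rays per
  query point and takes the majority parity vote, making the penetration
  count robust to edge-grazing rays; closedness (every edge shared by
  exactly two faces) is checked first.
* Keyword I/O accepts comma-separated and fixed-width dialects, preserves
  external IDs and connectivity verbatim (including collapsed records),
  and writes coordinates with 9 significant digits (round-trip ≤1e-8
  relative).

## Known limitations

* Uniform inverse-cubic weighting only; no anisotropic or cotangent
  schemes, and no soft (penalty) constraints.
* Extra-constraint candidate *selection* is advisory
  (`select_interface_candidates`) — the method, like the workflow it
  implements, relies on the user to choose where extra control is needed.
* Repair moves nodes only; it never changes topology, and clusters whose
  reference pool is degenerate are skipped and reported.
* Quality counts are convention-dependent (see above) and should not be
  compared across tools.
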