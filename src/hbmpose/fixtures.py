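"""Synthetic articulated limb fixtures and posing utilities.

Licensed production human body models cannot ship with this package, so the
test bed is a programmatically generated two-segment "limb" that reproduces
the structural features the positioning method must handle:

* a hexahedral **bone** core (a cortical tube, one per segment, the two
  segments topologically disconnected across the joint),
* a hexahedral **flesh** annulus running the full length and bending at the
  joint, separated from the bone by a thin cavity,
* a quadrilateral **skin** shell sharing the flesh's outer nodes,
* an optional disconnected **organ** inclusion resting in the cavity near
  the joint — anatomically adjacent to the bone but sharing no nodes with
  anything, the situation that forces extra constraints.

Target postures come from a one-hinge armature with linear blend skinning
(LBS): bone and organ nodes are bound rigidly to their segment, flesh and
skin blend across a transition band around the joint.  LBS's well-known
candy-wrapper pinching near the joint is intentional — it creates exactly
the distortions the Laplacian/repair stages are meant to survive.

A ray-parity point-in-polyhedron test provides the penetration count used
to validate positioning results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh_io import Element, FEMesh, SurfaceSet, extract_surface

__all__ = [
    "Joint",
    "Armature",
    "SkinWeights",
    "LimbFixtureSpec",
    "LimbFixture",
    "generate_limb",
    "pose_lbs",
    "count_penetrations",
    "points_inside_surface",
]


# ---------------------------------------------------------------------------
# armature + linear blend skinning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Joint:
    """A rotation about ``axis`` through ``pivot`` by ``angle_deg``."""

    pivot: tuple[float, float, float]
    axis: tuple[float, float, float]
    angle_deg: float = 0.0
    parent: int = -1


@dataclass
class Armature:
    """Ordered joint hierarchy rooted at a fixed base (parent = -1)."""

    joints: list[Joint]

    def __post_init__(self) -> None:
        for k, j in enumerate(self.joints):
            ax = np.asarray(j.axis, dtype=np.float64)
            if not np.isclose(np.linalg.norm(ax), 1.0, atol=1e-9):
                raise ValueError(f"joint {k}: axis must be unit-norm")
            if j.parent >= k:
                raise ValueError(f"joint {k}: parent must precede it (acyclic)")

    def with_angles(self, angles_deg) -> "Armature":
        return Armature(
            [replace(j, angle_deg=float(a)) for j, a in zip(self.joints, angles_deg)]
        )

    def world_transforms(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-joint (R, t) composed along the hierarchy: v -> R v + t."""
        out: list[tuple[np.ndarray, np.ndarray]] = []
        for j in self.joints:
            ax = np.asarray(j.axis, dtype=np.float64)
            th = np.deg2rad(j.angle_deg)
            K = np.array(
                [[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]]
            )
            R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
            p = np.asarray(j.pivot, dtype=np.float64)
            t = p - R @ p
            if j.parent >= 0:
                Rp, tp = out[j.parent]
                R, t = Rp @ R, Rp @ t + tp
            out.append((R, t))
        return out


@dataclass
class SkinWeights:
    """Per-node blend weights over the armature joints.

    Stored dense ``(n_nodes, n_joints)`` aligned with the mesh node order
    (two joints for the limb fixture); rows are >= 0 and sum to 1.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if (w < -1e-12).any():
            raise ValueError("negative skinning weight")
        self.weights = w

    def validate(self) -> None:
        sums = self.weights.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = np.flatnonzero(~np.isclose(sums, 1.0, atol=1e-9))
            raise ValueError(f"weights of {bad.size} node(s) do not sum to 1")


def pose_lbs(
    coords: np.ndarray, armature: Armature, weights: SkinWeights
) -> np.ndarray:
    """Linear blend skinning: weighted sum of per-joint rigid images."""
    coords = np.asarray(coords, dtype=np.float64)
    W = weights.weights
    if W.shape[0] != coords.shape[0]:
        raise ValueError("weights do not cover all queried nodes")
    sums = W.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("node(s) without full skinning weights")
    out = np.zeros_like(coords)
    for k, (R, t) in enumerate(armature.world_transforms()):
        wk = W[:, k]
        if (wk == 0).all():
            continue
        out += wk[:, None] * (coords @ R.T + t)
    return out


# ---------------------------------------------------------------------------
# limb generation
# ---------------------------------------------------------------------------


@dataclass
class LimbFixtureSpec:
    """Geometry and discretisation of the two-segment limb.

    Default dimensions are in mm and sized like a large human limb: two
    150 mm segments, a 10 mm-radius cortical bone tube, soft tissue out to
    a 25 mm skin radius.  The joint gap defaults to one skin radius so the
    rigid bone tips stay clear of the flexion crease; the skinning band
    defaults to ~1.8 limb diameters, wide enough that the blended target
    posture is volume-positive everywhere (a physically realizable target)
    at a 90 degree bend while still pinching hard at the joint.  Narrower
    bands sharpen the crease and stress the deformation and repair stages
    harder.
    """

    seg_length: float = 150.0
    bone_r_inner: float = 6.0
    bone_r_outer: float = 10.0
    flesh_r_inner: float = 14.0
    skin_r: float = 25.0
    n_circ: int = 32
    flesh_n_radial: int = 5
    flesh_n_axial_per_seg: int = 32
    bone_n_radial: int = 2
    bone_n_axial_per_seg: int = 24
    bone_end_margin: float = 5.0
    joint_gap: float = 25.0
    band: float = 90.0
    include_organ: bool = True
    organ_size: float = 3.0
    organ_divisions: int = 3
    organ_clearance: float = 0.5
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        radii = (
            self.bone_r_inner,
            self.bone_r_outer,
            self.flesh_r_inner,
            self.skin_r,
        )
        if not all(a < b for a, b in zip(radii, radii[1:])):
            raise ValueError("radii must be strictly nested")
        if min(
            self.n_circ,
            self.flesh_n_radial,
            self.flesh_n_axial_per_seg,
            self.bone_n_radial,
            self.bone_n_axial_per_seg,
        ) < 1 or self.n_circ < 8:
            raise ValueError("divisions too coarse")


@dataclass
class LimbFixture:
    """A generated limb plus everything needed to pose and validate it."""

    mesh: FEMesh
    parts: dict[str, int]
    armature: Armature
    weights: SkinWeights
    interface_ids: dict[str, np.ndarray]
    spec: LimbFixtureSpec
    skin_cap_faces: list[tuple[int, ...]] = field(default_factory=list)

    def posed_coords(self, angle_deg: float) -> np.ndarray:
        arm = self.armature.with_angles([0.0, angle_deg])
        return pose_lbs(self.mesh.coords, arm, self.weights)

    def closed_skin_surface(self) -> SurfaceSet:
        """Skin shell plus end-cap polygons: a watertight outer envelope."""
        skin_faces = [
            el.distinct_nodes
            for el in self.mesh.shells
            if el.pid == self.parts["skin"]
        ]
        faces = skin_faces + list(self.skin_cap_faces)
        nodes = sorted({n for f in faces for n in f})
        return SurfaceSet("skin_closed", np.array(nodes, np.int64), faces)


def _annulus_grid(
    radii: np.ndarray, n_circ: int, zs: np.ndarray, next_id: int
):
    """Structured cylindrical node grid; returns (ids, coords, id array)."""
    nr, nz = radii.size, zs.size
    ids = np.arange(next_id, next_id + nr * n_circ * nz).reshape(nr, n_circ, nz)
    theta = 2 * np.pi * np.arange(n_circ) / n_circ
    r, th, z = np.meshgrid(radii, theta, zs, indexing="ij")
    coords = np.stack(
        [r * np.cos(th), r * np.sin(th), z], axis=-1
    ).reshape(-1, 3)
    return ids, coords


def _annulus_hexes(ids: np.ndarray, eid0: int, pid: int) -> list[Element]:
    nr, nc, nz = ids.shape
    out = []
    eid = eid0
    for ir in range(nr - 1):
        for ic in range(nc):
            icn = (ic + 1) % nc
            for iz in range(nz - 1):
                n = (
                    ids[ir, ic, iz],
                    ids[ir + 1, ic, iz],
                    ids[ir + 1, icn, iz],
                    ids[ir, icn, iz],
                    ids[ir, ic, iz + 1],
                    ids[ir + 1, ic, iz + 1],
                    ids[ir + 1, icn, iz + 1],
                    ids[ir, icn, iz + 1],
                )
                out.append(Element(eid, pid, tuple(int(x) for x in n)))
                eid += 1
    return out


def generate_limb(spec: LimbFixtureSpec | None = None) -> LimbFixture:
    """Build the layered two-segment limb (deterministic for a fixed seed).

    Part IDs: 1 bone, 2 flesh, 3 skin, 4 organ.  The skin shell reuses the
    flesh's outer node layer; bone segments and the organ share no nodes
    with anything else.  Ground-truth interface node IDs (flesh inner
    surface near the joint; the organ face closest to the bone; the organ
    boundary) are recorded for constraint selection and validation.
    """
    spec = spec or LimbFixtureSpec()
    L = spec.seg_length
    total = 2 * L
    rng = np.random.default_rng(spec.seed)

    node_ids: list[np.ndarray] = []
    coords: list[np.ndarray] = []
    solids: list[Element] = []
    shells: list[Element] = []
    next_nid, next_eid = 1, 1

    # ---- flesh annulus (full length, bends at the joint) ----
    f_radii = np.linspace(spec.flesh_r_inner, spec.skin_r, spec.flesh_n_radial + 1)
    nzf = 2 * spec.flesh_n_axial_per_seg
    f_zs = np.linspace(0.0, total, nzf + 1)
    f_ids, f_xyz = _annulus_grid(f_radii, spec.n_circ, f_zs, next_nid)
    next_nid += f_xyz.shape[0]
    if spec.jitter > 0:
        # roughen interior flesh nodes only; surfaces stay exact
        jit = rng.normal(scale=spec.jitter, size=f_xyz.shape)
        mask = np.zeros(f_ids.shape, dtype=bool)
        mask[1:-1, :, 1:-1] = True
        f_xyz = f_xyz + jit * mask.reshape(-1)[:, None]
    node_ids.append(f_ids.reshape(-1))
    coords.append(f_xyz)
    flesh_elems = _annulus_hexes(f_ids, next_eid, pid=2)
    solids += flesh_elems
    next_eid += len(flesh_elems)

    # ---- skin shell on the flesh's outer node layer ----
    outer = f_ids[-1]
    for ic in range(spec.n_circ):
        icn = (ic + 1) % spec.n_circ
        for iz in range(nzf):
            shells.append(
                Element(
                    next_eid,
                    3,
                    (
                        int(outer[ic, iz]),
                        int(outer[icn, iz]),
                        int(outer[icn, iz + 1]),
                        int(outer[ic, iz + 1]),
                    ),
                )
            )
            next_eid += 1
    skin_cap_faces = [
        tuple(int(outer[ic, 0]) for ic in range(spec.n_circ))[::-1],
        tuple(int(outer[ic, -1]) for ic in range(spec.n_circ)),
    ]

    # ---- bone tubes, one per segment ----
    b_radii = np.linspace(spec.bone_r_inner, spec.bone_r_outer, spec.bone_n_radial + 1)
    for z0, z1 in (
        (spec.bone_end_margin, L - spec.joint_gap),
        (L + spec.joint_gap, total - spec.bone_end_margin),
    ):
        b_zs = np.linspace(z0, z1, spec.bone_n_axial_per_seg + 1)
        b_ids, b_xyz = _annulus_grid(b_radii, spec.n_circ, b_zs, next_nid)
        next_nid += b_xyz.shape[0]
        node_ids.append(b_ids.reshape(-1))
        coords.append(b_xyz)
        elems = _annulus_hexes(b_ids, next_eid, pid=1)
        solids += elems
        next_eid += len(elems)

    # ---- organ inclusion in the bone/flesh cavity near the joint ----
    organ_ids_grid = None
    if spec.include_organ:
        s = spec.organ_size
        nd = spec.organ_divisions
        y0 = spec.bone_r_outer + spec.organ_clearance
        if y0 + s >= spec.flesh_r_inner:
            raise ValueError("organ does not fit in the bone/flesh cavity")
        # rest against the distal bone segment, just past the joint gap
        zc = L + spec.joint_gap + s / 2 + 1.0
        xs = np.linspace(-s / 2, s / 2, nd + 1)
        ys = np.linspace(y0, y0 + s, nd + 1)
        zs = np.linspace(zc - s / 2, zc + s / 2, nd + 1)
        o_ids = np.arange(
            next_nid, next_nid + (nd + 1) ** 3
        ).reshape(nd + 1, nd + 1, nd + 1)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        o_xyz = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
        next_nid += o_xyz.shape[0]
        node_ids.append(o_ids.reshape(-1))
        coords.append(o_xyz)
        for i in range(nd):
            for jj in range(nd):
                for kk in range(nd):
                    n = (
                        o_ids[i, jj, kk],
                        o_ids[i + 1, jj, kk],
                        o_ids[i + 1, jj + 1, kk],
                        o_ids[i, jj + 1, kk],
                        o_ids[i, jj, kk + 1],
                        o_ids[i + 1, jj, kk + 1],
                        o_ids[i + 1, jj + 1, kk + 1],
                        o_ids[i, jj + 1, kk + 1],
                    )
                    solids.append(Element(next_eid, 4, tuple(int(x) for x in n)))
                    next_eid += 1
        organ_ids_grid = o_ids

    part_names = {1: "bone", 2: "flesh", 3: "skin"}
    if spec.include_organ:
        part_names[4] = "organ"
    mesh = FEMesh(
        node_ids=np.concatenate(node_ids),
        coords=np.concatenate(coords),
        solids=solids,
        shells=shells,
        part_names=part_names,
    )

    # ---- armature + weights ----
    armature = Armature(
        [
            Joint(pivot=(0.0, 0.0, 0.0), axis=(1.0, 0.0, 0.0), parent=-1),
            Joint(pivot=(0.0, 0.0, L), axis=(1.0, 0.0, 0.0), parent=0),
        ]
    )
    z = mesh.coords[:, 2]
    t = np.clip((z - (L - spec.band / 2)) / spec.band, 0.0, 1.0)
    s_blend = t * t * (3 - 2 * t)  # smoothstep across the band
    pid_of_node = np.zeros(mesh.n_nodes, dtype=np.int64)
    for el in mesh.solids:
        for n in el.nodes:
            pid_of_node[mesh._id_to_index[n]] = el.pid
    rigid = (pid_of_node == 1) | (pid_of_node == 4)
    s_blend = np.where(rigid, (z > L).astype(float), s_blend)
    weights = SkinWeights(np.stack([1.0 - s_blend, s_blend], axis=1))
    weights.validate()

    # ---- ground-truth interface IDs ----
    joint_ids = f_ids[0][
        :, np.abs(f_zs - L) <= spec.band
    ].reshape(-1)
    end_ids = np.concatenate(
        [f_ids[:-1, :, 0].reshape(-1), f_ids[:-1, :, -1].reshape(-1)]
    )
    interface: dict[str, np.ndarray] = {
        "joint": np.sort(joint_ids.astype(np.int64)),
        # inner cylinder wall, end rings excluded (they lie on the end caps)
        "flesh_inner": np.sort(f_ids[0][:, 1:-1].reshape(-1).astype(np.int64)),
        # open end planes (minus the constrained skin ring): free boundaries
        # that drift under rotation because differential coordinates are not
        # rotation-invariant; standard extra-constraint targets
        "ends": np.sort(end_ids.astype(np.int64)),
    }
    if organ_ids_grid is not None:
        bone_face = organ_ids_grid[:, 0, :].reshape(-1)  # face nearest the bone
        nd = spec.organ_divisions
        boundary = np.zeros(organ_ids_grid.shape, dtype=bool)
        boundary[0, :, :] = boundary[-1, :, :] = True
        boundary[:, 0, :] = boundary[:, -1, :] = True
        boundary[:, :, 0] = boundary[:, :, -1] = True
        interface["organ"] = np.sort(bone_face.astype(np.int64))
        interface["organ_surface"] = np.sort(
            organ_ids_grid[boundary].astype(np.int64)
        )

    return LimbFixture(
        mesh=mesh,
        parts={v: k for k, v in part_names.items()},
        armature=armature,
        weights=weights,
        interface_ids=interface,
        spec=spec,
        skin_cap_faces=skin_cap_faces,
    )


# ---------------------------------------------------------------------------
# penetration checking (ray parity)
# ---------------------------------------------------------------------------


def _check_closed(faces) -> None:
    edge_count: dict[tuple[int, int], int] = {}
    for f in faces:
        k = len(f)
        for i in range(k):
            e = tuple(sorted((int(f[i]), int(f[(i + 1) % k]))))
            edge_count[e] = edge_count.get(e, 0) + 1
    bad = [e for e, c in edge_count.items() if c != 2]
    if bad:
        raise ValueError(
            f"outer surface not closed: {len(bad)} edge(s) not shared by "
            f"exactly two faces (e.g. {bad[:3]})"
        )


def _triangulate(faces, order: dict[int, int]) -> np.ndarray:
    tris = []
    for f in faces:
        idx = [order[int(n)] for n in f]
        for k in range(1, len(idx) - 1):
            tris.append((idx[0], idx[k], idx[k + 1]))
    return np.asarray(tris, dtype=np.int64)


def points_inside_surface(
    points: np.ndarray,
    surface: SurfaceSet,
    surface_coords: np.ndarray,
    seed: int = 0,
    n_rays: int = 3,
) -> np.ndarray:
    """Ray-parity inside test against a closed, consistently meshed surface.

    Fires ``n_rays`` independent random ray directions per point and takes
    the majority inside/outside verdict, which makes the test robust to
    rays grazing edges.  ``surface_coords`` aligns with
    ``surface.node_ids``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    _check_closed(surface.faces)
    order = {int(n): k for k, n in enumerate(surface.node_ids)}
    tris = _triangulate(surface.faces, order)
    V = np.asarray(surface_coords, dtype=np.float64)
    v0 = V[tris[:, 0]]
    e1 = V[tris[:, 1]] - v0
    e2 = V[tris[:, 2]] - v0

    rng = np.random.default_rng(seed)
    votes = np.zeros(points.shape[0], dtype=np.int64)
    for _ in range(n_rays):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        h = np.cross(d, e2)
        a = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(a) > 1e-14
        f = np.where(ok, 1.0 / np.where(a == 0, 1.0, a), 0.0)
        crossings = np.zeros(points.shape[0], dtype=np.int64)
        chunk = max(1, int(1e6 // max(tris.shape[0], 1)))
        for lo in range(0, points.shape[0], chunk):
            P = points[lo : lo + chunk]
            s = P[:, None, :] - v0[None, :, :]
            u = f * np.einsum("ptj,tj->pt", s, h)
            q = np.cross(s, e1[None, :, :])
            v = f * np.einsum("ptj,j->pt", q, d)
            tpar = f * np.einsum("ptj,tj->pt", q, e2)
            hit = (
                ok[None, :]
                & (u >= 0.0)
                & (v >= 0.0)
                & (u + v <= 1.0)
                & (tpar > 1e-9)
            )
            crossings[lo : lo + chunk] = hit.sum(axis=1)
        votes += crossings % 2
    return votes * 2 > n_rays


def count_penetrations(
    inner,
    outer,
    mode: str = "outside",
    seed: int = 0,
) -> int:
    """Count inner-surface nodes on the wrong side of a closed outer surface.

    ``inner`` is either a plain ``(k, 3)`` point array or a
    ``(SurfaceSet, coords)`` pair; ``outer`` must be a closed
    ``(SurfaceSet, coords)`` pair.  ``mode="outside"`` counts inner nodes
    strictly outside the envelope (e.g. soft tissue escaping the skin);
    ``mode="inside"`` counts nodes inside (e.g. tissue swallowed by the
    bone — "inside the wrong part").
    """
    if isinstance(inner, tuple):
        _, pts = inner
    else:
        pts = inner
    surf, coords = outer
    inside = points_inside_surface(pts, surf, coords, seed=seed)
    if mode == "outside":
        return int((~inside).sum())
    if mode == "inside":
        return int(inside.sum())
    raise ValueError("mode must be 'outside' or 'inside'")
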