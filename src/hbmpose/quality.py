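"""Per-element quality metrics: scaled Jacobian and edge aspect ratio.

Conventions
-----------
* Hexahedra: at each of the 8 corners, the Jacobian is the determinant of
  the three emanating edge vectors, each normalised to unit length; the
  element value is the minimum over corners.  A perfect cube scores 1, a
  fully inverted element -1; J < 0 means negative volume.
* Tetrahedra: determinant of the three unit edge vectors from the first
  node, divided by sqrt(2)/2 so the regular tetrahedron scores 1.
* Shells: the analogous 2-D corner test on the element plane (corner cross
  product against the element normal); triangles are normalised by
  sqrt(3)/2 so the equilateral triangle scores 1.
* Aspect ratio: longest edge / shortest edge over the element edge set.
* Beams carry neutral values (J = 1, AR = 1) and never enter the counts.

Elements with a zero-length edge are flagged degenerate (J evaluated on the
remaining distinct corners for collapsed hexes; AR = +inf when an edge of a
nominally non-collapsed element has zero length).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mesh_io import FEMesh

__all__ = [
    "QualityReport",
    "scaled_jacobian",
    "aspect_ratio",
    "quality_report",
    "hex_scaled_jacobian",
    "tet_scaled_jacobian",
    "shell_scaled_jacobian",
]

# corner -> the three adjacent corners, ordered so a right-handed hex
# (solver node ordering) gives +1 determinants on the unit cube
_HEX_CORNERS = (
    (0, (1, 3, 4)),
    (1, (2, 0, 5)),
    (2, (3, 1, 6)),
    (3, (0, 2, 7)),
    (4, (7, 5, 0)),
    (5, (4, 6, 1)),
    (6, (5, 7, 2)),
    (7, (6, 4, 3)),
)

_HEX_EDGES = (
    (0, 1), (1, 2), (2, 3), (3, 0),
    (4, 5), (5, 6), (6, 7), (7, 4),
    (0, 4), (1, 5), (2, 6), (3, 7),
)
_TET_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
_QUAD_EDGES = ((0, 1), (1, 2), (2, 3), (3, 0))
_TRI_EDGES = ((0, 1), (1, 2), (2, 0))

_TET_IDEAL = np.sqrt(2.0) / 2.0  # det of unit edge frame of the regular tet
_TRI_IDEAL = np.sqrt(3.0) / 2.0


def _unit(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalise along the last axis; returns (unit vectors, zero-mask)."""
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    zero = n[..., 0] == 0
    n = np.where(n == 0, 1.0, n)
    return v / n, zero


def hex_scaled_jacobian(X: np.ndarray) -> np.ndarray:
    """Min corner scaled Jacobian for hex8 coordinate arrays ``(m, 8, 3)``.

    Corners touching a zero-length edge (collapsed records) are skipped; an
    element with no valid corner scores 0.
    """
    X = np.asarray(X, dtype=np.float64)
    m = X.shape[0]
    J = np.full((m, 8), np.inf)
    valid_any = np.zeros(m, dtype=bool)
    for k, (c, (a, b, d)) in enumerate(_HEX_CORNERS):
        e1, z1 = _unit(X[:, a] - X[:, c])
        e2, z2 = _unit(X[:, b] - X[:, c])
        e3, z3 = _unit(X[:, d] - X[:, c])
        det = np.einsum("ij,ij->i", np.cross(e1, e2), e3)
        bad = z1 | z2 | z3
        J[:, k] = np.where(bad, np.inf, det)
        valid_any |= ~bad
    out = J.min(axis=1)
    out[~valid_any] = 0.0
    return out


def tet_scaled_jacobian(X: np.ndarray) -> np.ndarray:
    """Scaled Jacobian for tet4 coordinate arrays ``(m, 4, 3)``."""
    X = np.asarray(X, dtype=np.float64)
    e1, z1 = _unit(X[:, 1] - X[:, 0])
    e2, z2 = _unit(X[:, 2] - X[:, 0])
    e3, z3 = _unit(X[:, 3] - X[:, 0])
    det = np.einsum("ij,ij->i", np.cross(e1, e2), e3) / _TET_IDEAL
    det[z1 | z2 | z3] = 0.0
    return det


def shell_scaled_jacobian(X: np.ndarray, is_tri: np.ndarray) -> np.ndarray:
    """Corner Jacobian for shells ``(m, 4, 3)`` (tris padded on node 3)."""
    X = np.asarray(X, dtype=np.float64)
    m = X.shape[0]
    out = np.empty(m)
    # element normal: quads from diagonals, tris from two edges
    d1 = np.where(is_tri[:, None], X[:, 1] - X[:, 0], X[:, 2] - X[:, 0])
    d2 = np.where(is_tri[:, None], X[:, 2] - X[:, 0], X[:, 3] - X[:, 1])
    nrm, zn = _unit(np.cross(d1, d2))
    for tri in (False, True):
        sel = np.flatnonzero(is_tri == tri)
        if sel.size == 0:
            continue
        k = 3 if tri else 4
        corners = np.full((sel.size, k), np.inf)
        ok_any = np.zeros(sel.size, dtype=bool)
        for c in range(k):
            a, b = (c + 1) % k, (c - 1) % k
            e1, z1 = _unit(X[sel, a] - X[sel, c])
            e2, z2 = _unit(X[sel, b] - X[sel, c])
            det = np.einsum("ij,ij->i", np.cross(e1, e2), nrm[sel])
            bad = z1 | z2 | zn[sel]
            corners[:, c] = np.where(bad, np.inf, det)
            ok_any |= ~bad
        vals = corners.min(axis=1)
        vals[~ok_any] = 0.0
        if tri:
            vals = vals / _TRI_IDEAL
        out[sel] = vals
    return out


def _edge_ratio(X: np.ndarray, edges) -> np.ndarray:
    lens = np.stack(
        [np.linalg.norm(X[:, b] - X[:, a], axis=1) for a, b in edges], axis=1
    )
    lo = lens.min(axis=1)
    hi = lens.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ar = np.where(lo > 0, hi / np.where(lo == 0, 1, lo), np.inf)
    return ar


def scaled_jacobian(coords: np.ndarray) -> float:
    """Scaled Jacobian of a single element given its corner coordinates.

    The element type is inferred from the corner count: 8 -> hex (collapsed
    hexes handled), 4 -> tet, shells via 4 coplanar/3 corners are dispatched
    by :func:`quality_report`; for a standalone call a 4-corner element is
    treated as a tet.
    """
    X = np.asarray(coords, dtype=np.float64)
    if X.shape == (8, 3):
        return float(hex_scaled_jacobian(X[None])[0])
    if X.shape == (4, 3):
        return float(tet_scaled_jacobian(X[None])[0])
    if X.shape == (3, 3):
        Xp = np.concatenate([X, X[2:3]], axis=0)
        return float(
            shell_scaled_jacobian(Xp[None], np.array([True]))[0]
        )
    raise ValueError(f"unsupported element shape {X.shape}")


def aspect_ratio(coords: np.ndarray) -> float:
    """Longest/shortest edge of a single element (hex, tet, quad or tri)."""
    X = np.asarray(coords, dtype=np.float64)
    table = {8: _HEX_EDGES, 4: _TET_EDGES, 3: _TRI_EDGES}
    if X.shape[0] == 4 and X.ndim == 2:
        # ambiguous quad-vs-tet: tets are volumetric; pick by caller context.
        table[4] = _TET_EDGES
    edges = table[X.shape[0]]
    return float(_edge_ratio(X[None], edges)[0])


@dataclass
class QualityReport:
    """Per-element metric arrays and the three threshold counts."""

    kinds: np.ndarray  # "solid" | "shell" per evaluated element
    eids: np.ndarray
    pids: np.ndarray
    jacobian: np.ndarray
    aspect: np.ndarray
    j_threshold: float = 0.3
    ar_threshold: float = 10.0
    degenerate: np.ndarray = field(default=None)

    def n_j_below(self, threshold: float | None = None) -> int:
        t = self.j_threshold if threshold is None else threshold
        return int((self.jacobian < t).sum())

    @property
    def n_negative_volume(self) -> int:
        return int((self.jacobian < 0.0).sum())

    def n_ar_above(self, threshold: float | None = None) -> int:
        t = self.ar_threshold if threshold is None else threshold
        return int((self.aspect > t).sum())

    def summary(self) -> dict:
        return {
            "n_elements": int(self.jacobian.size),
            "n_J_below": self.n_j_below(),
            "n_negative_volume": self.n_negative_volume,
            "n_AR_above": self.n_ar_above(),
            "thresholds": {"J": self.j_threshold, "AR": self.ar_threshold},
        }

    def distorted_mask(self, threshold: float | None = None) -> np.ndarray:
        t = self.j_threshold if threshold is None else threshold
        return self.jacobian < t

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["eid", "kind", "pid", "jacobian", "aspect_ratio"])
            for k in range(self.eids.size):
                w.writerow(
                    [
                        int(self.eids[k]),
                        self.kinds[k],
                        int(self.pids[k]),
                        f"{self.jacobian[k]:.8g}",
                        f"{self.aspect[k]:.8g}",
                    ]
                )


def quality_report(
    mesh: FEMesh,
    coords: np.ndarray | None = None,
    j_threshold: float = 0.3,
    ar_threshold: float = 10.0,
    csv_path: str | Path | None = None,
) -> QualityReport:
    """Evaluate all solids and shells of the mesh.

    ``coords`` overrides the mesh's own coordinates (e.g. a positioned
    state).  Results are deterministic for a fixed mesh.
    """
    V = mesh.coords if coords is None else np.asarray(coords, dtype=np.float64)
    kinds, eids, pids, J, AR, degen = [], [], [], [], [], []

    if mesh.solids:
        s_eids, s_pids, conn, ndist = mesh.solid_arrays()
        X = V[conn]
        is_tet = np.array(
            [len(el.nodes) == 4 for el in mesh.solids], dtype=bool
        )
        j = np.empty(len(mesh.solids))
        a = np.empty(len(mesh.solids))
        if is_tet.any():
            j[is_tet] = tet_scaled_jacobian(X[is_tet][:, :4])
            a[is_tet] = _edge_ratio(X[is_tet][:, :4], _TET_EDGES)
        hex_idx = np.flatnonzero(~is_tet)
        if hex_idx.size:
            j[hex_idx] = hex_scaled_jacobian(X[hex_idx])
            a[hex_idx] = _edge_ratio(X[hex_idx], _HEX_EDGES)
            # collapsed hexes: measure edges among distinct nodes only
            for k in hex_idx[ndist[hex_idx] < 8]:
                dn = mesh.solids[k].distinct_nodes
                Xd = V[mesh.index_of(dn)]
                lens = [
                    float(np.linalg.norm(Xd[i] - Xd[jj]))
                    for i in range(len(dn))
                    for jj in range(i + 1, len(dn))
                ]
                lens = [x for x in lens if x > 0]
                a[k] = max(lens) / min(lens) if lens else np.inf
        kinds += ["solid"] * len(mesh.solids)
        eids.append(s_eids)
        pids.append(s_pids)
        J.append(j)
        AR.append(a)
        degen.append(ndist < (np.where(is_tet, 4, 8)))

    if mesh.shells:
        h_eids, h_pids, conn, ndist = mesh.shell_arrays()
        X = V[conn]
        is_tri = ndist == 3
        j = shell_scaled_jacobian(X, is_tri)
        a = np.empty(len(mesh.shells))
        if is_tri.any():
            a[is_tri] = _edge_ratio(X[is_tri][:, :3], _TRI_EDGES)
        if (~is_tri).any():
            a[~is_tri] = _edge_ratio(X[~is_tri], _QUAD_EDGES)
        kinds += ["shell"] * len(mesh.shells)
        eids.append(h_eids)
        pids.append(h_pids)
        J.append(j)
        AR.append(a)
        degen.append(ndist < 3)

    if not kinds:
        raise ValueError("mesh has no solid or shell elements")

    report = QualityReport(
        kinds=np.array(kinds),
        eids=np.concatenate(eids),
        pids=np.concatenate(pids),
        jacobian=np.concatenate(J),
        aspect=np.concatenate(AR),
        j_threshold=j_threshold,
        ar_threshold=ar_threshold,
        degenerate=np.concatenate(degen),
    )
    if csv_path is not None:
        report.to_csv(csv_path)
    return report
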