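"""Read, write and interrogate volumetric finite-element meshes.

The on-disk format is the solver-keyword text dialect that production human
body models ship in: ``*NODE`` blocks with node IDs and coordinates, and
``*ELEMENT_SOLID`` / ``*ELEMENT_SHELL`` / ``*ELEMENT_BEAM`` blocks with
element ID, part ID and connectivity.  Both the classic fixed-width layout
(8-character integer fields, 16-character coordinate fields) and the
comma-separated layout are accepted.  Keywords outside this subset
(materials, sections, contacts ...) are skipped with a warning so that real
decks remain readable.

External node IDs are 1-based and preserved verbatim; internally the mesh
keeps a dense 0-based index with an explicit bidirectional map so the linear
algebra downstream stays simple.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Element",
    "FEMesh",
    "SurfaceSet",
    "read_keyword_mesh",
    "write_keyword_mesh",
    "extract_surface",
    "export_surface_obj",
    "read_obj_vertices",
    "write_vtk",
    "HEX_FACES",
    "TET_FACES",
]

# Outward-oriented faces for the solver hex8 corner ordering
# (nodes 1-4 bottom face, 5-8 top face).
HEX_FACES = (
    (0, 3, 2, 1),
    (4, 5, 6, 7),
    (0, 1, 5, 4),
    (1, 2, 6, 5),
    (2, 3, 7, 6),
    (3, 0, 4, 7),
)
TET_FACES = ((0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2))


@dataclass(frozen=True)
class Element:
    """One finite element: external ID, part ID and external connectivity."""

    eid: int
    pid: int
    nodes: tuple[int, ...]

    @property
    def distinct_nodes(self) -> tuple[int, ...]:
        seen: dict[int, None] = {}
        for n in self.nodes:
            seen.setdefault(n)
        return tuple(seen)

    @property
    def is_degenerate(self) -> bool:
        """True for collapsed records (repeated node IDs)."""
        return len(set(self.nodes)) < len(self.nodes)


@dataclass
class FEMesh:
    """A volumetric FE model: nodes plus typed elements grouped in parts.

    ``node_ids`` are the external (file) IDs in file order; ``coords`` is the
    aligned ``(n, 3)`` coordinate array (length units, mm by convention).
    """

    node_ids: np.ndarray
    coords: np.ndarray
    solids: list[Element] = field(default_factory=list)
    shells: list[Element] = field(default_factory=list)
    beams: list[Element] = field(default_factory=list)
    part_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if self.node_ids.shape[0] != self.coords.shape[0]:
            raise ValueError("node_ids and coords lengths differ")
        ids, counts = np.unique(self.node_ids, return_counts=True)
        if (counts > 1).any():
            dup = int(ids[counts > 1][0])
            raise ValueError(f"duplicate node ID {dup}")
        self._id_to_index = {int(i): k for k, i in enumerate(self.node_ids)}
        for el in self.iter_elements():
            for nid in el.nodes:
                if nid not in self._id_to_index:
                    raise ValueError(
                        f"element {el.eid} references missing node {nid}"
                    )

    # -- indexing ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.node_ids.shape[0]

    def index_of(self, ids: Iterable[int]) -> np.ndarray:
        """Map external node IDs to dense 0-based indices."""
        return np.fromiter(
            (self._id_to_index[int(i)] for i in ids), dtype=np.int64
        )

    def iter_elements(self) -> Iterable[Element]:
        yield from self.solids
        yield from self.shells
        yield from self.beams

    @property
    def part_of_element(self) -> dict[tuple[str, int], int]:
        out: dict[tuple[str, int], int] = {}
        for kind, group in (
            ("solid", self.solids),
            ("shell", self.shells),
            ("beam", self.beams),
        ):
            for el in group:
                out[(kind, el.eid)] = el.pid
        return out

    def part_ids(self) -> set[int]:
        ids = {el.pid for el in self.iter_elements()}
        ids.update(self.part_names)
        return ids

    def bbox_diagonal(self) -> float:
        span = self.coords.max(axis=0) - self.coords.min(axis=0)
        return float(np.linalg.norm(span))

    def with_coords(self, coords: np.ndarray) -> "FEMesh":
        """A shallow copy of the mesh carrying new node coordinates."""
        return replace(self, coords=np.array(coords, dtype=np.float64))

    # -- padded connectivity for vectorised metrics -----------------------
    def solid_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Solids as ``(eids, pids, conn8, n_distinct)`` with internal indices.

        Tetrahedra (4-node records) are padded by repeating their last node,
        the collapsed-hex convention; ``n_distinct`` distinguishes the cases.
        """
        m = len(self.solids)
        eids = np.empty(m, np.int64)
        pids = np.empty(m, np.int64)
        conn = np.empty((m, 8), np.int64)
        ndist = np.empty(m, np.int64)
        for k, el in enumerate(self.solids):
            eids[k], pids[k] = el.eid, el.pid
            nodes = el.nodes
            if len(nodes) == 4:
                nodes = nodes + (nodes[3],) * 4
            conn[k] = [self._id_to_index[n] for n in nodes]
            ndist[k] = len(el.distinct_nodes)
        return eids, pids, conn, ndist

    def shell_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Shells as ``(eids, pids, conn4, n_distinct)`` (tris pad node 3)."""
        m = len(self.shells)
        eids = np.empty(m, np.int64)
        pids = np.empty(m, np.int64)
        conn = np.empty((m, 4), np.int64)
        ndist = np.empty(m, np.int64)
        for k, el in enumerate(self.shells):
            eids[k], pids[k] = el.eid, el.pid
            nodes = el.nodes
            if len(nodes) == 3:
                nodes = nodes + (nodes[2],)
            conn[k] = [self._id_to_index[n] for n in nodes]
            ndist[k] = len(el.distinct_nodes)
        return eids, pids, conn, ndist


@dataclass
class SurfaceSet:
    """Boundary surface of a part group: faces plus their node-ID set."""

    name: str
    node_ids: np.ndarray  # sorted external node IDs
    faces: list[tuple[int, ...]]  # external node IDs, outward oriented

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return self.node_ids.shape[0]

    def coords(self, mesh: FEMesh) -> np.ndarray:
        return mesh.coords[mesh.index_of(self.node_ids)]


# ---------------------------------------------------------------------------
# keyword file reading
# ---------------------------------------------------------------------------

_KNOWN_PREFIXES = (
    "*NODE",
    "*ELEMENT_SOLID",
    "*ELEMENT_SHELL",
    "*ELEMENT_BEAM",
    "*PART",
    "*KEYWORD",
    "*END",
    "*TITLE",
)


def _split_fields(
    line: str, widths: Sequence[int], expect: int | None = None
) -> list[str]:
    """Tokenise one data line: comma, whitespace, then fixed-width fallback.

    Fixed-width layouts can run fields together (a negative number filling
    its column), so when whitespace splitting yields fewer than ``expect``
    tokens the line is re-read by column widths.
    """
    if "," in line:
        return [t.strip() for t in line.split(",")]
    toks = line.split()
    if len(toks) >= (expect or 2):
        return toks
    out, pos = [], 0
    for w in widths:
        if pos >= len(line):
            break
        out.append(line[pos : pos + w].strip())
        pos += w
    return [t for t in out if t]


def read_keyword_mesh(path: str | Path) -> FEMesh:
    """Parse a keyword deck into an :class:`FEMesh`.

    Accepts ``*NODE``, ``*ELEMENT_SOLID``, ``*ELEMENT_SHELL``,
    ``*ELEMENT_BEAM`` and ``*PART``; other keywords are skipped with a
    warning.  Comment lines start with ``$``.
    """
    path = Path(path)
    text = path.read_text()
    node_ids: list[int] = []
    coords: list[tuple[float, float, float]] = []
    solids: list[Element] = []
    shells: list[Element] = []
    beams: list[Element] = []
    part_names: dict[int, str] = {}
    seen_ids: set[int] = set()

    current = None
    part_title: str | None = None
    skipped: set[str] = set()

    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("$"):
            continue
        if line.lstrip().startswith("*"):
            kw = line.strip().upper()
            if kw.startswith("*NODE"):
                current = "node"
            elif kw.startswith("*ELEMENT_SOLID"):
                current = "solid"
            elif kw.startswith("*ELEMENT_SHELL"):
                current = "shell"
            elif kw.startswith("*ELEMENT_BEAM"):
                current = "beam"
            elif kw.startswith("*PART"):
                current = "part"
                part_title = None
            elif kw in ("*KEYWORD", "*TITLE") or kw.startswith("*END"):
                current = "skip" if kw == "*TITLE" else None
            else:
                if kw not in skipped:
                    skipped.add(kw)
                    log.warning("skipping unknown keyword block %s", kw)
                current = None
            continue
        if current is None:
            continue
        if current == "skip":
            continue
        if current == "node":
            f = _split_fields(line, (8, 16, 16, 16), expect=4)
            nid = int(f[0])
            if nid in seen_ids:
                raise ValueError(f"duplicate node ID {nid}")
            seen_ids.add(nid)
            node_ids.append(nid)
            coords.append((float(f[1]), float(f[2]), float(f[3])))
        elif current == "solid":
            f = _split_fields(line, (8,) * 10)
            vals = [int(t) for t in f if t]
            eid, pid, nodes = vals[0], vals[1], tuple(vals[2:])
            if len(nodes) not in (4, 8):
                raise ValueError(
                    f"solid {eid}: expected 4 or 8 nodes, got {len(nodes)}"
                )
            solids.append(Element(eid, pid, nodes))
        elif current == "shell":
            f = _split_fields(line, (8,) * 6)
            vals = [int(t) for t in f if t]
            eid, pid, nodes = vals[0], vals[1], tuple(vals[2:6])
            if len(nodes) not in (3, 4):
                raise ValueError(
                    f"shell {eid}: expected 3 or 4 nodes, got {len(nodes)}"
                )
            shells.append(Element(eid, pid, nodes))
        elif current == "beam":
            f = _split_fields(line, (8,) * 5)
            vals = [int(t) for t in f if t]
            eid, pid, nodes = vals[0], vals[1], tuple(vals[2:4])
            beams.append(Element(eid, pid, nodes))
        elif current == "part":
            if part_title is None:
                # first data card of *PART is the title
                stripped = line.strip()
                try:
                    pid = int(stripped.split(",")[0].split()[0])
                except (ValueError, IndexError):
                    part_title = stripped
                    continue
                # numeric first card: title omitted
                part_names[pid] = f"part_{pid}"
                part_title = ""
            else:
                pid = int(line.split(",")[0].split()[0])
                part_names[pid] = part_title or f"part_{pid}"
                part_title = None

    if not node_ids:
        raise ValueError(f"{path}: no *NODE data found")
    return FEMesh(
        node_ids=np.array(node_ids, dtype=np.int64),
        coords=np.array(coords, dtype=np.float64),
        solids=solids,
        shells=shells,
        beams=beams,
        part_names=part_names,
    )


def write_keyword_mesh(mesh: FEMesh, path: str | Path) -> None:
    """Write the mesh as a fixed-width keyword deck.

    External IDs, part IDs and corner ordering are preserved verbatim
    (including collapsed/degenerate connectivity); coordinates are printed
    with 9 significant digits so a read-back reproduces them to better than
    1e-8 relative.
    """
    path = Path(path)
    lines = ["*KEYWORD"]
    for pid in sorted(mesh.part_names):
        lines.append("*PART")
        lines.append(mesh.part_names[pid])
        lines.append(f"{pid:10d}")
    lines.append("*NODE")
    for nid, (x, y, z) in zip(mesh.node_ids, mesh.coords):
        lines.append(f"{int(nid):8d}{x:16.8e}{y:16.8e}{z:16.8e}")
    for kw, group in (
        ("*ELEMENT_SOLID", mesh.solids),
        ("*ELEMENT_SHELL", mesh.shells),
        ("*ELEMENT_BEAM", mesh.beams),
    ):
        if not group:
            continue
        lines.append(kw)
        for el in group:
            conn = "".join(f"{n:8d}" for n in el.nodes)
            lines.append(f"{el.eid:8d}{el.pid:8d}{conn}")
    lines.append("*END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# surface extraction
# ---------------------------------------------------------------------------


def _element_faces(el: Element) -> list[tuple[int, ...]]:
    faces = []
    if len(el.nodes) == 8:
        tables = HEX_FACES
    else:
        tables = TET_FACES
    for tab in tables:
        face = tuple(el.nodes[i] for i in tab)
        # drop collapsed faces (fewer than 3 distinct corners)
        distinct = tuple(dict.fromkeys(face))
        if len(distinct) >= 3:
            faces.append(distinct)
    return faces


def extract_surface(
    mesh: FEMesh, part_ids: Iterable[int], name: str = "surface"
) -> SurfaceSet:
    """Boundary surface of a part group.

    Solid faces referenced exactly once within the group are boundary faces;
    parts that contain shells but no solids contribute all their shells.
    Face identity is the sorted node-ID tuple, so the result is independent
    of element ordering and face orientation.
    """
    part_ids = set(int(p) for p in part_ids)
    unknown = part_ids - mesh.part_ids()
    if unknown:
        raise KeyError(f"unknown part IDs: {sorted(unknown)}")

    counts: dict[tuple[int, ...], tuple[int, ...]] = {}
    nref: dict[tuple[int, ...], int] = {}
    for el in mesh.solids:
        if el.pid not in part_ids:
            continue
        for face in _element_faces(el):
            key = tuple(sorted(face))
            nref[key] = nref.get(key, 0) + 1
            counts.setdefault(key, face)
    faces = [counts[k] for k in sorted(counts) if nref[k] == 1]

    solid_pids = {el.pid for el in mesh.solids}
    for el in mesh.shells:
        if el.pid in part_ids and el.pid not in solid_pids:
            faces.append(el.distinct_nodes)

    nodes = sorted({n for f in faces for n in f})
    return SurfaceSet(name=name, node_ids=np.array(nodes, np.int64), faces=faces)


# ---------------------------------------------------------------------------
# OBJ export / import for posing round trips
# ---------------------------------------------------------------------------


def export_surface_obj(
    surface: SurfaceSet, mesh: FEMesh, path: str | Path
) -> Path:
    """Write a surface as Wavefront OBJ plus a JSON sidecar index map.

    The sidecar (``<path>.map.json``) records OBJ vertex order -> external
    node ID so vertices of a posed copy of the OBJ can be mapped back onto
    mesh constraints.
    Returns the sidecar path.
    """
    path = Path(path)
    order = {int(n): k for k, n in enumerate(surface.node_ids)}
    for f in surface.faces:
        for n in f:
            if n not in order:
                raise ValueError(f"face references node {n} outside surface")
    coords = surface.coords(mesh)
    lines = [f"v {x:.10g} {y:.10g} {z:.10g}" for x, y, z in coords]
    for f in surface.faces:
        lines.append("f " + " ".join(str(order[n] + 1) for n in f))
    path.write_text("\n".join(lines) + "\n")
    sidecar = path.with_suffix(path.suffix + ".map.json")
    sidecar.write_text(
        json.dumps({"obj_to_node": [int(n) for n in surface.node_ids]})
    )
    return sidecar


def read_obj_vertices(path: str | Path) -> np.ndarray:
    """Vertex coordinates of an OBJ file, in file order."""
    verts = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("v "):
            parts = line.split()
            verts.append([float(parts[1]), float(parts[2]), float(parts[3])])
    return np.asarray(verts, dtype=np.float64)


def write_vtk(mesh: FEMesh, path: str | Path) -> None:
    """Legacy-ASCII VTK unstructured-grid export, for visual inspection only."""
    path = Path(path)
    cells = []
    types = []
    for el in mesh.solids:
        idx = mesh.index_of(el.nodes)
        if len(el.nodes) == 8:
            cells.append(idx)
            types.append(12)  # VTK_HEXAHEDRON
        else:
            cells.append(idx)
            types.append(10)  # VTK_TETRA
    for el in mesh.shells:
        idx = mesh.index_of(el.distinct_nodes)
        cells.append(idx)
        types.append(9 if len(idx) == 4 else 5)
    for el in mesh.beams:
        cells.append(mesh.index_of(el.nodes))
        types.append(3)
    out = [
        "# vtk DataFile Version 3.0",
        "hbmpose export",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    out += [f"{x:.10g} {y:.10g} {z:.10g}" for x, y, z in mesh.coords]
    total = sum(len(c) + 1 for c in cells)
    out.append(f"CELLS {len(cells)} {total}")
    out += [f"{len(c)} " + " ".join(map(str, c)) for c in cells]
    out.append(f"CELL_TYPES {len(cells)}")
    out += [str(t) for t in types]
    path.write_text("\n".join(out) + "\n")
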