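import numpy as np
import pytest

from hbmpose.fixtures import LimbFixtureSpec, generate_limb
from hbmpose.mesh_io import Element, FEMesh

# unit cube in solver hex8 corner ordering (bottom face, then top face)
UNIT_CUBE = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=float,
)


def make_hex_mesh(coords, pid=1, part_name="block"):
    """Single-hex FEMesh from 8 corner coordinates."""
    return FEMesh(
        node_ids=np.arange(1, 9),
        coords=np.asarray(coords, dtype=float),
        solids=[Element(1, pid, tuple(range(1, 9)))],
        part_names={pid: part_name},
    )


def make_block_mesh(n=4, spacing=1.0, pid=1):
    """(n-1)^3-element structured hex block with n^3 nodes."""
    ids = np.arange(1, n**3 + 1).reshape(n, n, n)
    xs = np.arange(n, dtype=float) * spacing
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    coords = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    solids = []
    eid = 1
    for i in range(n - 1):
        for j in range(n - 1):
            for k in range(n - 1):
                conn = (
                    ids[i, j, k],
                    ids[i + 1, j, k],
                    ids[i + 1, j + 1, k],
                    ids[i, j + 1, k],
                    ids[i, j, k + 1],
                    ids[i + 1, j, k + 1],
                    ids[i + 1, j + 1, k + 1],
                    ids[i, j + 1, k + 1],
                )
                solids.append(Element(eid, pid, tuple(int(x) for x in conn)))
                eid += 1
    return FEMesh(
        node_ids=ids.reshape(-1),
        coords=coords,
        solids=solids,
        part_names={pid: "block"},
    ), ids


SMALL_SPEC_KW = dict(
    n_circ=16,
    flesh_n_radial=3,
    flesh_n_axial_per_seg=12,
    bone_n_radial=1,
    bone_n_axial_per_seg=10,
)


@pytest.fixture(scope="session")
def small_limb():
    """Coarse limb (~1.9k elements) for fast end-to-end tests."""
    return generate_limb(LimbFixtureSpec(**SMALL_SPEC_KW))


@pytest.fixture(scope="session")
def small_limb_no_organ():
    return generate_limb(LimbFixtureSpec(include_organ=False, **SMALL_SPEC_KW))


@pytest.fixture(scope="session")
def default_limb():
    """The full-size study fixture (~15.4k elements)."""
    return generate_limb(LimbFixtureSpec())
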